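"""Parameter estimation from observation tables.

The objective is least squares on the log scale,

    L(theta) = sum_rows (log(value + eps) - log(prediction + eps))^2,

which is the maximum-likelihood objective (up to constants) under the
generator's multiplicative lognormal noise.  Predictions come from
integrating the chosen model from its basal equilibrium, per genotype
present in the data.  Full 15-parameter fitting is not identifiable from
five observables at four time points; fit small subsets (e.g. {k1, d1})
with the rest fixed.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

from .core import Genotype, ModelKind, ModelParameters, RATE_NAMES, SignalProfile
from .synthetic_data import Observable, ObservationTable, observe
from .simulate import initial_condition_basal, integrate
from .core import State

__all__ = ["FitSpec", "FitResult", "loss", "fit"]

_LOG_EPS = 1e-9


@dataclasses.dataclass(frozen=True)
class FitSpec:
    """Which parameters to estimate, within what bounds, around what base.

    ``fixed_values`` supplies every parameter not being estimated (and the
    model kind); ``free_parameters`` are overridden by the candidate.
    All parameters are shared across genotypes except the S513A zeroing of
    d7, d8, d9, which is applied per data row's genotype.
    """

    free_parameters: tuple[str, ...]
    bounds: Mapping[str, tuple[float, float]]
    fixed_values: ModelParameters
    model: ModelKind
    shared_across_genotypes: bool = True

    def __post_init__(self) -> None:
        free = tuple(self.free_parameters)
        if not free:
            raise ValueError("free_parameters must be nonempty")
        unknown = set(free) - set(RATE_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter names {sorted(unknown)}")
        object.__setattr__(self, "free_parameters", free)
        bounds = {name: (float(lo), float(hi)) for name, (lo, hi) in self.bounds.items()}
        for name in free:
            if name not in bounds:
                raise ValueError(f"no bounds given for free parameter {name!r}")
            lo, hi = bounds[name]
            if not (0 <= lo < hi):
                raise ValueError(f"bounds for {name!r} must satisfy 0 <= lo < hi")
        object.__setattr__(self, "bounds", bounds)
        if not isinstance(self.model, ModelKind):
            object.__setattr__(self, "model", ModelKind(self.model))

    def build_params(self, candidate: Mapping[str, float]) -> ModelParameters:
        overrides = {name: float(candidate[name]) for name in self.free_parameters}
        return self.fixed_values.replace(kind=self.model, **overrides)

    @classmethod
    def from_dict(cls, doc: dict) -> "FitSpec":
        return cls(
            free_parameters=tuple(doc["free_parameters"]),
            bounds={k: tuple(v) for k, v in doc["bounds"].items()},
            fixed_values=ModelParameters.from_dict(doc["fixed_values"]),
            model=ModelKind(doc["model"]),
            shared_across_genotypes=bool(doc.get("shared_across_genotypes", True)),
        )


@dataclasses.dataclass(frozen=True)
class FitResult:
    """Point estimates plus bookkeeping from the minimization."""

    estimates: dict[str, float]
    loss_value: float
    converged: bool
    n_evaluations: int

    def to_dict(self) -> dict:
        return {
            "estimates": dict(self.estimates),
            "loss_value": self.loss_value,
            "converged": self.converged,
            "n_evaluations": self.n_evaluations,
        }


def _check_candidate(spec: FitSpec, candidate: Mapping[str, float]) -> None:
    for name in spec.free_parameters:
        lo, hi = spec.bounds[name]
        v = float(candidate[name])
        if not (lo <= v <= hi):
            raise ValueError(f"candidate {name}={v} outside bounds [{lo}, {hi}]")


def _genotypes_in(data: ObservationTable) -> list[Genotype]:
    return [Genotype(g) for g in data.data["genotype"].unique()]


def loss(
    spec: FitSpec,
    candidate: Mapping[str, float],
    data: ObservationTable,
    profile: SignalProfile,
) -> float:
    """Sum of squared log-residuals of the candidate against the table.

    Returns +inf (candidate rejected, never an exception) when the
    candidate makes the basal equilibrium degenerate or the integration
    fail.
    """
    _check_candidate(spec, candidate)
    if len(data.data) == 0:
        raise ValueError("observation table is empty")
    genotypes = _genotypes_in(data)
    if genotypes == [Genotype.S513A] and not set(spec.free_parameters).isdisjoint(
        {"d7", "d8", "d9"}
    ):
        raise ValueError(
            "d7/d8/d9 are unidentifiable from S513A data alone (zeroed by genotype)"
        )
    params = spec.build_params(candidate)
    total = 0.0
    for genotype in genotypes:
        sub = data.data[data.data["genotype"] == genotype.value]
        times = np.asarray(sorted(sub["time"].unique()), dtype=float)
        try:
            x0 = initial_condition_basal(params, genotype, profile.s_base)
            if times.size < 2:
                states = {float(times[0]): x0}  # only reachable for t=0 tables
            else:
                tc = integrate(params, genotype, profile, x0, float(times[-1]), times)
                states = {
                    float(t): State.from_array(row)
                    for t, row in zip(tc.times, tc.states)
                }
        except Exception:
            return math.inf
        for _, row in sub.iterrows():
            pred = observe(states[float(row["time"])], Observable(row["observable"]))
            r = math.log(row["value"] + _LOG_EPS) - math.log(pred + _LOG_EPS)
            total += r * r
    return total


def fit(
    spec: FitSpec,
    data: ObservationTable,
    profile: SignalProfile,
    start: Mapping[str, float],
    seed: int = 0,
    n_starts: int = 3,
) -> FitResult:
    """Bounded local minimization of :func:`loss`, with seeded restarts.

    The first start is the one supplied; additional starts perturb it by
    lognormal factors (geometric sd 2) clipped into the bounds.  Each
    start runs a derivative-free Powell search; the best result is
    returned.  Reproducible from ``seed``.
    """
    _check_candidate(spec, start)
    names = spec.free_parameters
    lo = np.array([spec.bounds[n][0] for n in names])
    hi = np.array([spec.bounds[n][1] for n in names])
    x_start = np.array([float(start[n]) for n in names])
    rng = np.random.default_rng(seed)
    n_evals = 0

    def objective(x: np.ndarray) -> float:
        nonlocal n_evals
        n_evals += 1
        cand = dict(zip(names, np.clip(x, lo, hi)))
        return loss(spec, cand, data, profile)

    starts = [x_start]
    for _ in range(max(0, int(n_starts) - 1)):
        perturbed = x_start * rng.lognormal(mean=0.0, sigma=math.log(2.0), size=len(names))
        starts.append(np.clip(perturbed, lo + 1e-12, hi))

    best_x, best_f, any_success = None, math.inf, False
    for x0 in starts:
        res = optimize.minimize(
            objective,
            x0,
            method="Powell",
            bounds=optimize.Bounds(lo, hi),
            options={"xtol": 1e-10, "ftol": 1e-12, "maxiter": 2000},
        )
        if math.isfinite(res.fun) and res.fun < best_f:
            best_x, best_f = np.clip(res.x, lo, hi), float(res.fun)
            any_success = bool(res.success) or any_success
    if best_x is None:
        best_x, best_f, any_success = x_start, objective(x_start), False
    return FitResult(
        estimates={n: float(v) for n, v in zip(names, best_x)},
        loss_value=best_f,
        converged=any_success and math.isfinite(best_f),
        n_evaluations=n_evals,
    )
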