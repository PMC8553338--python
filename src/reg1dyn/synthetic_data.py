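"""Synthetic two-genotype observation tables.

Emulates the study design the models were built against: immunoblot
readouts of total Regnase-1 protein and of its fast-/slow-migrating
fractions (free vs. 14-3-3-bound), and RT-qPCR of *Il6* and *Zc3h12a*
mRNA, measured at a handful of time points after stimulation in wild-type
and S513A cells, with a few biological replicates per condition.

Measurement noise is multiplicative lognormal (densitometry and qPCR are
positive, roughly log-scale measurements), parameterized by its
coefficient of variation with mean exactly 1: the underlying normal has
sigma^2 = ln(1 + cv^2) and mu = -sigma^2/2.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    Genotype,
    ModelParameters,
    SignalProfile,
    State,
    apply_genotype,
)
from .simulate import initial_condition_basal, integrate

__all__ = [
    "Observable",
    "NoiseSpec",
    "ObservationTable",
    "observe",
    "lognormal_noise_params",
    "generate_dataset",
    "DEFAULT_SAMPLE_TIMES",
]

#: Sampling times (hours) matching the study's immunoblot/qPCR design.
DEFAULT_SAMPLE_TIMES = (0.0, 0.5, 2.0, 4.0)


class Observable(enum.Enum):
    """Measured quantity, as a deterministic projection of the state."""

    TOTAL_REG1 = "total_reg1"      # x3 + x4 (whole immunoblot band mass)
    FREE_REG1 = "free_reg1"        # x3 (fast-migrating band)
    BOUND_REG1 = "bound_reg1"      # x4 (slow-migrating band; synthetic-only
    #                                convenience, the study reads it only as
    #                                a gel shift)
    IL6_MRNA = "il6_mrna"          # x1
    ZC3H12A_MRNA = "zc3h12a_mrna"  # x2


@dataclasses.dataclass(frozen=True)
class NoiseSpec:
    """Multiplicative lognormal measurement noise, seeded and replicated."""

    cv: float = 0.1
    seed: int = 0
    replicates: int = 3

    def __post_init__(self) -> None:
        if not (self.cv >= 0) or math.isinf(self.cv):
            raise ValueError(f"cv must be a finite nonnegative number, got {self.cv!r}")
        if int(self.replicates) < 1:
            raise ValueError(f"replicates must be >= 1, got {self.replicates!r}")
        object.__setattr__(self, "replicates", int(self.replicates))
        object.__setattr__(self, "seed", int(self.seed))

    def to_dict(self) -> dict:
        return {"cv": self.cv, "seed": self.seed, "replicates": self.replicates}


def observe(state: State, observable: Observable) -> float:
    """Project a model state onto one measured quantity."""
    observable = Observable(observable)
    if observable is Observable.TOTAL_REG1:
        return state.x3 + state.x4
    if observable is Observable.FREE_REG1:
        return state.x3
    if observable is Observable.BOUND_REG1:
        return state.x4
    if observable is Observable.IL6_MRNA:
        return state.x1
    return state.x2


def lognormal_noise_params(cv: float) -> tuple[float, float]:
    """(mu, sigma) of the underlying normal for mean-1 lognormal noise."""
    sigma2 = math.log1p(cv * cv)
    return -0.5 * sigma2, math.sqrt(sigma2)


@dataclasses.dataclass(frozen=True)
class ObservationTable:
    """Synthetic measurements plus the provenance that generated them.

    ``data`` has columns genotype, time, observable, replicate, value;
    one row per simulated measurement.
    """

    data: pd.DataFrame
    params_wt: ModelParameters
    params_sa: ModelParameters
    profile: SignalProfile
    noise: NoiseSpec

    COLUMNS = ("genotype", "time", "observable", "replicate", "value")

    def values(
        self,
        genotype: Genotype,
        observable: Observable,
        time: float | None = None,
    ) -> np.ndarray:
        """Replicate values for one cell (or one genotype/observable pair)."""
        mask = (self.data["genotype"] == genotype.value) & (
            self.data["observable"] == observable.value
        )
        if time is not None:
            mask &= np.isclose(self.data["time"], time)
        return self.data.loc[mask, "value"].to_numpy()

    def to_csv(self, path) -> None:
        """Write the table as CSV plus a sidecar JSON provenance file."""
        path = Path(path)
        self.data.to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".provenance.json")
        doc = {
            "params_wt": self.params_wt.to_dict(Genotype.WT),
            "params_sa": self.params_sa.to_dict(Genotype.S513A),
            "profile": self.profile.to_dict(),
            "noise": self.noise.to_dict(),
        }
        sidecar.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_csv(cls, path) -> "ObservationTable":
        path = Path(path)
        data = pd.read_csv(path)
        missing = set(cls.COLUMNS) - set(data.columns)
        if missing:
            raise ValueError(f"observation table is missing columns {sorted(missing)}")
        sidecar = path.with_suffix(path.suffix + ".provenance.json")
        doc = json.loads(sidecar.read_text())
        return cls(
            data=data[list(cls.COLUMNS)],
            params_wt=ModelParameters.from_dict(doc["params_wt"]),
            params_sa=ModelParameters.from_dict(doc["params_sa"]),
            profile=SignalProfile.from_dict(doc["profile"]),
            noise=NoiseSpec(**doc["noise"]),
        )


def _simulate_states(
    params: ModelParameters,
    genotype: Genotype,
    profile: SignalProfile,
    sample_times: np.ndarray,
) -> list[State]:
    p = apply_genotype(params, genotype)
    x0 = initial_condition_basal(p, genotype, profile.s_base)
    tc = integrate(p, genotype, profile, x0, float(sample_times[-1]), sample_times)
    return [State.from_array(row) for row in tc.states]


def generate_dataset(
    params_wt: ModelParameters,
    params_sa: ModelParameters,
    profile: SignalProfile,
    sample_times: Sequence[float] = DEFAULT_SAMPLE_TIMES,
    noise: NoiseSpec = NoiseSpec(),
) -> ObservationTable:
    """Simulate both genotypes from rest and emit a noisy observation table.

    Each genotype is integrated from its basal equilibrium under the pulse
    profile and sampled at ``sample_times``; every (time, observable) cell
    receives ``noise.replicates`` independent lognormal factors with mean 1
    and coefficient of variation ``noise.cv``.  Identical ``noise.seed``
    gives an identical table; cv = 0 gives the noiseless model projections
    exactly.
    """
    times = np.asarray(sorted(set(float(t) for t in sample_times)), dtype=float)
    if times.size == 0:
        raise ValueError("sample_times must be nonempty")
    if times.size == 1 or not (times[-1] > 0):
        raise ValueError("sample_times must span a positive interval")
    rng = np.random.default_rng(noise.seed)
    mu, sigma = lognormal_noise_params(noise.cv)
    rows: list[tuple] = []
    for genotype, params in ((Genotype.WT, params_wt), (Genotype.S513A, params_sa)):
        states = _simulate_states(params, genotype, profile, times)
        for t, state in zip(times, states):
            for observable in Observable:
                clean = observe(state, observable)
                for rep in range(noise.replicates):
                    factor = 1.0 if noise.cv == 0.0 else float(
                        rng.lognormal(mean=mu, sigma=sigma)
                    )
                    rows.append(
                        (genotype.value, t, observable.value, rep, clean * factor)
                    )
    data = pd.DataFrame(rows, columns=list(ObservationTable.COLUMNS))
    return ObservationTable(
        data=data,
        params_wt=params_wt,
        params_sa=apply_genotype(params_sa, Genotype.S513A),
        profile=profile,
        noise=noise,
    )
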