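"""Closed-form fixed points of both models, and a numeric root oracle.

Setting the four derivatives to zero under a constant signal ``s`` reduces
each model to a single quadratic.  For the wild type the free-protein
fixed point X3 solves

    (d2 + (d7 s/(d8+d9)) d2p) K X3^2 + d5 K X3 - k2 s = 0,

with the composite constant

    K = (d3 + d6 s + d7 s - d7 d9 s / (d8 + d9)) / k3

(obtained by substituting the bound-pool balance X4 = d7 s X3/(d8+d9)
into the protein equation), and X4 = (d7 s/(d8+d9)) X3, X2 = K X3,
X1 = k1 s/(d1 X3 + d1p X4 + d4).  A nonnegative equilibrium exists iff
K >= 0, and for nonnegative rate constants K >= 0 always holds (the
subtracted fraction never exceeds d7 s).  For S513A (d7 = d8 = d9 = 0) the reduced system gives X4 = 0 and
a quadratic in X2 instead; that branch always has a nonnegative solution.
"""

from __future__ import annotations

import dataclasses
import enum
import math

import numpy as np
from scipy import optimize

from .core import Genotype, ModelParameters, State, _rhs_array, apply_genotype

__all__ = [
    "DegenerateParameterError",
    "ConvergenceError",
    "EquilibriumBranch",
    "EquilibriumResult",
    "effective_K",
    "equilibrium_closed_form",
    "equilibrium_numeric_oracle",
    "solve_k2_for_target_x3",
]


class DegenerateParameterError(ValueError):
    """Parameter combination for which the closed form is undefined."""


class ConvergenceError(RuntimeError):
    """The numeric root iteration failed to reach the residual tolerance."""


class EquilibriumBranch(enum.Enum):
    """Which closed-form system produced the fixed point."""

    WT_GENERAL = "wt_general"
    S513A_REDUCED = "s513a_reduced"


@dataclasses.dataclass(frozen=True)
class EquilibriumResult:
    """Fixed point of either model under sustained stimulation.

    ``exists`` is False only when K < 0 (unreachable for nonnegative rate
    constants, but kept representable because existence is an
    if-and-only-if condition on K); the components are then NaN.
    """

    X1: float
    X2: float
    X3: float
    X4: float
    K: float
    exists: bool
    branch: EquilibriumBranch

    def as_state(self) -> State:
        if not self.exists:
            raise ValueError("no equilibrium exists (K < 0)")
        return State(self.X1, self.X2, self.X3, self.X4)

    def to_dict(self) -> dict:
        return {
            "X1": self.X1, "X2": self.X2, "X3": self.X3, "X4": self.X4,
            "K": self.K, "exists": self.exists, "branch": self.branch.value,
        }


def effective_K(params: ModelParameters, s_input: float) -> float:
    """The composite constant K governing the equilibrium quadratic.

    K = (1/k3) * (d3 + d6 s + d7 s - d7 d9 s / (d8 + d9)), with the
    subtracted fraction read as 0 when d8 + d9 = 0 (its numerator also
    vanishes there).  Algebraically
    d7 s - d7 d9 s/(d8 + d9) = d7 s d8/(d8 + d9) >= 0, so K >= 0 for any
    nonnegative parameters with k3 > 0: a nonnegative equilibrium always
    exists in the biologically meaningful parameter region.
    """
    s = float(s_input)
    if s < 0:
        raise ValueError(f"s_input must be nonnegative, got {s!r}")
    if params.k3 == 0:
        raise DegenerateParameterError("k3 = 0: no translation, K undefined")
    den = params.d8 + params.d9
    frac = 0.0 if den == 0 else params.d7 * params.d9 * s / den
    return (params.d3 + params.d6 * s + params.d7 * s - frac) / params.k3


def _positive_quadratic_root(a: float, b: float, c: float) -> float:
    """Unique nonnegative root of a x^2 + b x + c = 0 with a, b >= 0, c <= 0.

    Uses the cancellation-free form x = -2c / (b + sqrt(b^2 - 4ac)); since
    c <= 0 the discriminant is >= b^2 and the root is well conditioned even
    when b dominates.
    """
    disc = b * b - 4.0 * a * c
    denom = b + math.sqrt(disc)
    if denom == 0.0:
        if c == 0.0:
            return 0.0
        raise DegenerateParameterError(
            "quadratic has no nonnegative root (all coefficients vanish "
            "except a positive constant term)"
        )
    return -2.0 * c / denom


def _reduced_equilibrium(p: ModelParameters, s: float, K: float) -> EquilibriumResult:
    """Fixed point of the no-binding system (d7 = d8 = d9 = 0 effective)."""
    den = p.d3 + p.d6 * s
    if den == 0.0:
        if p.k2 * s == 0.0 and p.k1 * s == 0.0:
            # no transcription and no protein turnover: x3 is undetermined
            raise DegenerateParameterError(
                "d3 + d6*s = 0 with zero transcription: equilibrium not unique"
            )
        raise DegenerateParameterError(
            "d3 + d6*s = 0: protein never degrades, no finite equilibrium"
        )
    a = p.d2 * p.k3 / den
    X2 = _positive_quadratic_root(a, p.d5, -p.k2 * s)
    X3 = p.k3 / den * X2
    num = p.k1 * s
    den1 = p.d1 * X3 + p.d4
    if num == 0.0:
        X1 = 0.0
    elif den1 == 0.0:
        raise DegenerateParameterError(
            "Il6 mRNA has no degradation path (d1*X3 + d4 = 0) but is transcribed"
        )
    else:
        X1 = num / den1
    return EquilibriumResult(X1, X2, X3, 0.0, K, True, EquilibriumBranch.S513A_REDUCED)


def equilibrium_closed_form(
    params: ModelParameters, genotype: Genotype, s_input: float
) -> EquilibriumResult:
    """Closed-form nonnegative equilibrium at constant signal ``s_input``.

    Applies the genotype first (S513A zeroes d7, d8, d9), then dispatches:
    the general branch when the bound complex turns over (d8 + d9 > 0),
    the reduced branch when there is no binding at all (d7 s = 0 with
    d8 + d9 = 0, which covers S513A).  The corner d8 + d9 = 0 with
    d7 s > 0 (complex forms but neither degrades nor dissociates) has no
    finite X4 and is rejected.

    Model 1 is covered by the same formulas with d1p = d2p = 0.
    """
    p = apply_genotype(params, genotype)
    s = float(s_input)
    if s < 0:
        raise ValueError(f"s_input must be nonnegative, got {s!r}")
    K = effective_K(p, s)
    if K < 0:
        return EquilibriumResult(
            math.nan, math.nan, math.nan, math.nan, K, False,
            EquilibriumBranch.WT_GENERAL,
        )
    d89 = p.d8 + p.d9
    if d89 == 0.0:
        if p.d7 * s > 0.0:
            raise DegenerateParameterError(
                "d8 + d9 = 0 with d7*s > 0: bound Regnase-1 neither degrades "
                "nor dissociates, X4 closed form undefined"
            )
        return _reduced_equilibrium(p, s, K)
    ratio = p.d7 * s / d89
    a = (p.d2 + ratio * p.d2p) * K
    X3 = _positive_quadratic_root(a, p.d5 * K, -p.k2 * s)
    X4 = ratio * X3
    X2 = K * X3
    num = p.k1 * s
    den1 = p.d1 * X3 + p.d1p * X4 + p.d4
    if num == 0.0:
        X1 = 0.0
    elif den1 == 0.0:
        raise DegenerateParameterError(
            "Il6 mRNA has no degradation path but is transcribed"
        )
    else:
        X1 = num / den1
    return EquilibriumResult(X1, X2, X3, X4, K, True, EquilibriumBranch.WT_GENERAL)


def equilibrium_numeric_oracle(
    params: ModelParameters,
    genotype: Genotype,
    s_input: float,
    x0: State,
    residual_tol: float = 1e-10,
    max_iter: int = 400,
) -> State:
    """Root of rhs = 0 at fixed signal, by damped iteration with projection.

    Independent of the closed forms: runs MINPACK's damped hybrid
    (Powell) iteration on the right-hand side evaluated at the state
    projected onto the nonnegative orthant, retrying from rescaled starts
    if needed, and accepts only a projected root whose residual infinity
    norm is below ``residual_tol``.

    When the bound pool has no flux at all (d7*s = 0 and d8 + d9 = 0,
    e.g. the S513A genotype), x4 is a conserved quantity and the root
    manifold is a line; the biologically meaningful equilibrium pins
    x4 = 0 (no complex ever forms) and the remaining three equations are
    solved alone.

    Raises
    ------
    ConvergenceError
        If no start reaches the residual tolerance.
    """
    p = apply_genotype(params, genotype)
    s = float(s_input)
    if s < 0:
        raise ValueError(f"s_input must be nonnegative, got {s!r}")
    base = x0.as_array()
    x4_conserved = p.d7 * s == 0.0 and p.d8 + p.d9 == 0.0

    def fun(x: np.ndarray) -> np.ndarray:
        return _rhs_array(p, np.maximum(x, 0.0), s)

    def fun3(x3vec: np.ndarray) -> np.ndarray:
        full = np.append(x3vec, 0.0)
        return fun(full)[:3]

    best_res = math.inf
    for scale in (1.0, 0.1, 10.0, 0.01):
        start = base * scale if np.any(base > 0) else np.full(4, scale)
        if x4_conserved:
            sol = optimize.root(fun3, start[:3], method="hybr",
                                options={"xtol": 1e-13, "maxfev": max_iter * 3})
            sol_x = np.append(sol.x, 0.0)
        else:
            sol = optimize.root(fun, start, method="hybr",
                                options={"xtol": 1e-13, "maxfev": max_iter * 4})
            sol_x = sol.x
        root = np.maximum(sol_x, 0.0)
        res = float(np.max(np.abs(fun(root))))
        if res < best_res:
            best_res = res
        if res < residual_tol:
            return State.from_array(root)
    raise ConvergenceError(
        f"root iteration did not reach residual {residual_tol:g} "
        f"(best {best_res:g})"
    )


def solve_k2_for_target_x3(
    params: ModelParameters,
    genotype: Genotype,
    s_input: float,
    target_X3: float,
) -> float:
    """The *Zc3h12a* transcription rate k2 that places the equilibrium free
    Regnase-1 at ``target_X3``.

    The equilibrium quadratic is linear in k2, so the answer is a direct
    evaluation of its left-hand side at the target.  Used to engineer a
    wild-type parameter set whose free-protein fixed point matches a given
    S513A one (the matched-free-Regnase-1 condition of the discrimination
    argument).
    """
    p = apply_genotype(params, genotype)
    s = float(s_input)
    if not (s > 0):
        raise ValueError(f"s_input must be positive, got {s!r}")
    X3 = float(target_X3)
    if X3 < 0:
        raise ValueError(f"target_X3 must be nonnegative, got {X3!r}")
    K = effective_K(p, s)
    d89 = p.d8 + p.d9
    if d89 == 0.0:
        if p.d7 * s > 0.0:
            raise DegenerateParameterError(
                "d8 + d9 = 0 with d7*s > 0: closed form undefined"
            )
        den = p.d3 + p.d6 * s
        if den == 0.0:
            raise DegenerateParameterError("d3 + d6*s = 0: no finite equilibrium")
        X2 = den / p.k3 * X3
        return (p.d2 * p.k3 / den * X2 * X2 + p.d5 * X2) / s
    ratio = p.d7 * s / d89
    a = (p.d2 + ratio * p.d2p) * K
    return (a * X3 * X3 + p.d5 * K * X3) / s
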