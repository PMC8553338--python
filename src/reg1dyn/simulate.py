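"""Time integration of either model under the pulse signal.

Trajectories start from the basal equilibrium (resting cells before
stimulation) by default and are solved with a stiff-capable adaptive
integrator at tight tolerances; sampled states are clipped to the
nonnegative orthant on output.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .core import (
    Genotype,
    ModelParameters,
    SignalProfile,
    State,
    _rhs_array,
    apply_genotype,
    signal_at,
)
from .equilibrium import EquilibriumResult, equilibrium_closed_form

__all__ = [
    "IntegrationError",
    "TimeCourse",
    "initial_condition_basal",
    "integrate",
    "has_converged_to",
]

#: Solver tolerances (the contract is tolerance-based, not method-based).
RTOL = 1e-8
ATOL = 1e-10


class IntegrationError(RuntimeError):
    """The initial-value solver failed or produced an invalid trajectory."""


@dataclasses.dataclass(frozen=True)
class TimeCourse:
    """Sampled trajectory of one genotype under one signal profile."""

    times: np.ndarray
    states: np.ndarray  # shape (len(times), 4), clipped to >= 0
    params_used: ModelParameters
    profile_used: SignalProfile
    genotype: Genotype = Genotype.WT

    def final_state(self) -> State:
        return State.from_array(self.states[-1])

    def state_at(self, t: float) -> State:
        """State at a sampled time point (exact match required)."""
        idx = np.flatnonzero(np.isclose(self.times, t, rtol=0.0, atol=1e-12))
        if idx.size == 0:
            raise KeyError(f"time {t} was not sampled")
        return State.from_array(self.states[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with header time,x1,x2,x3,x4,signal."""
        sig = [signal_at(self.profile_used, t) for t in self.times]
        return pd.DataFrame(
            {
                "time": self.times,
                "x1": self.states[:, 0],
                "x2": self.states[:, 1],
                "x3": self.states[:, 2],
                "x4": self.states[:, 3],
                "signal": sig,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def initial_condition_basal(
    params: ModelParameters, genotype: Genotype, s_base: float
) -> State:
    """Resting-cell state: the closed-form equilibrium at the basal signal."""
    eq = equilibrium_closed_form(params, genotype, s_base)
    return eq.as_state()


def integrate(
    params: ModelParameters,
    genotype: Genotype,
    profile: SignalProfile,
    x0: State,
    t_end: float,
    output_times: Sequence[float],
) -> TimeCourse:
    """Solve the initial-value problem and sample it at ``output_times``.

    Uses LSODA (switches to a stiff BDF method automatically; degradation
    rates may span orders of magnitude) at rtol=1e-8, atol=1e-10.  The
    right-hand side is evaluated on the state projected onto the
    nonnegative orthant, which keeps round-off excursions below the
    absolute tolerance; sampled states more negative than -1e-9 abort the
    run, otherwise they are clipped to 0.

    Deterministic for fixed inputs.
    """
    t_end = float(t_end)
    if not (t_end > 0):
        raise ValueError(f"t_end must be positive, got {t_end!r}")
    times = np.asarray(output_times, dtype=float)
    if times.ndim != 1 or times.size < 2:
        raise ValueError("output_times must be a 1-D sequence with >= 2 points")
    if np.any(np.diff(times) <= 0):
        raise ValueError("output_times must be strictly increasing")
    if times[0] < 0 or times[-1] > t_end + 1e-12:
        raise ValueError("output_times must lie within [0, t_end]")
    p = apply_genotype(params, genotype)

    def fun(t: float, x: np.ndarray) -> np.ndarray:
        return _rhs_array(p, np.maximum(x, 0.0), signal_at(profile, t))

    sol = solve_ivp(
        fun,
        (0.0, t_end),
        x0.as_array(),
        method="LSODA",
        rtol=RTOL,
        atol=ATOL,
        t_eval=times,
        dense_output=False,
    )
    if not sol.success:
        raise IntegrationError(f"integration failed at t={sol.t[-1]!r}: {sol.message}")
    states = sol.y.T
    if np.min(states) < -1e-9:
        raise IntegrationError(
            f"trajectory left the nonnegative orthant (min {np.min(states):g})"
        )
    states = np.clip(states, 0.0, None)
    return TimeCourse(times=sol.t.copy(), states=states,
                      params_used=p, profile_used=profile, genotype=genotype)


def has_converged_to(
    tc: TimeCourse, eq: EquilibriumResult, rel_tol: float
) -> bool:
    """Whether the final sampled state matches the fixed point.

    Component-wise relative comparison; absolute comparison (|final| <
    rel_tol) where the target component is zero.
    """
    if not eq.exists:
        raise ValueError("equilibrium does not exist; nothing to converge to")
    final = tc.states[-1]
    target = np.array([eq.X1, eq.X2, eq.X3, eq.X4])
    for f, x in zip(final, target):
        if x == 0.0:
            if abs(f) > rel_tol:
                return False
        elif abs(f - x) / abs(x) > rel_tol:
            return False
    return True
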