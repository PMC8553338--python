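"""State space, parameters, stimulation signal and ODE right-hand sides.

Two competing models of stimulus-induced Regnase-1 regulation share one
four-dimensional state: *Il6* mRNA (x1), *Zc3h12a* mRNA (x2), free
Regnase-1 protein (x3) and 14-3-3-bound Regnase-1 protein (x4).  In
Model 1 the 14-3-3-bound protein is catalytically dead; Model 2 lets it
keep degrading the two target mRNAs (rate constants ``d1p``/``d2p``).
The S513A knock-in genotype abolishes 14-3-3 binding and is modelled by
zeroing the binding/complex rates ``d7``, ``d8``, ``d9``.

Time is measured in hours; signal strength and abundances are
dimensionless arbitrary units.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
from typing import Iterable

import numpy as np

__all__ = [
    "ModelKind",
    "Genotype",
    "PostPulseMode",
    "SignalProfile",
    "ModelParameters",
    "State",
    "RATE_NAMES",
    "signal_at",
    "apply_genotype",
    "rhs",
    "save_params",
    "load_params",
    "save_profile",
    "load_profile",
]

#: Names of all rate-constant fields on :class:`ModelParameters`, in
#: canonical serialization order.
RATE_NAMES = (
    "k1", "k2", "k3",
    "d1", "d2", "d1p", "d2p",
    "d3", "d4", "d5", "d6", "d7", "d8", "d9",
)


class ModelKind(enum.Enum):
    """Which hypothesis about 14-3-3-bound Regnase-1 the ODEs encode."""

    #: Bound Regnase-1 is inactive (no mRNA degradation by x4).
    MODEL_1 = "model1"
    #: Bound Regnase-1 retains target-mRNA degradation activity.
    MODEL_2 = "model2"


class Genotype(enum.Enum):
    """Wild type or the S513A knock-in (no 14-3-3 binding)."""

    WT = "WT"
    S513A = "S513A"


class PostPulseMode(enum.Enum):
    """Behaviour of the stimulation signal after the plateau ends."""

    #: Signal stays at ``s_input`` forever (the equilibrium assumption).
    SUSTAINED = "sustained"
    #: Signal relaxes exponentially back to ``s_base``.
    DECAYING = "decaying"


def _require_finite_nonneg(name: str, value: float) -> float:
    value = float(value)
    if math.isnan(value) or math.isinf(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    if value < 0:
        raise ValueError(f"{name} must be nonnegative, got {value!r}")
    return value


@dataclasses.dataclass(frozen=True)
class SignalProfile:
    """Delayed ramp-plateau pulse describing IL-1R/TLR stimulation strength.

    The signal sits at ``s_base`` until ``t_delay``, ramps linearly to
    ``s_input`` over ``t_raise`` hours, holds the plateau for ``t_pulse``
    hours, and afterwards either stays at ``s_input`` (SUSTAINED) or decays
    back to ``s_base`` with timescale ``t_decay`` (DECAYING).  All times in
    hours; signal strengths dimensionless.
    """

    s_base: float = 0.0
    s_input: float = 1.0
    t_delay: float = 0.25
    t_raise: float = 0.25
    t_pulse: float = 1.0
    post_pulse_mode: PostPulseMode = PostPulseMode.SUSTAINED
    t_decay: float = 1.0

    def __post_init__(self) -> None:
        for name in ("s_base", "s_input", "t_delay", "t_raise", "t_pulse"):
            object.__setattr__(
                self, name, _require_finite_nonneg(name, getattr(self, name))
            )
        if self.s_input < self.s_base:
            raise ValueError(
                f"s_input ({self.s_input}) must be >= s_base ({self.s_base})"
            )
        if not isinstance(self.post_pulse_mode, PostPulseMode):
            object.__setattr__(
                self, "post_pulse_mode", PostPulseMode(self.post_pulse_mode)
            )
        t_decay = float(self.t_decay)
        if not (t_decay > 0) or math.isinf(t_decay):
            raise ValueError(f"t_decay must be a positive finite number, got {t_decay!r}")
        object.__setattr__(self, "t_decay", t_decay)

    @property
    def t_pulse_end(self) -> float:
        """Time at which the plateau ends (hours)."""
        return self.t_delay + self.t_raise + self.t_pulse

    def to_dict(self) -> dict:
        return {
            "s_base": self.s_base,
            "s_input": self.s_input,
            "t_delay": self.t_delay,
            "t_raise": self.t_raise,
            "t_pulse": self.t_pulse,
            "post_pulse_mode": self.post_pulse_mode.value,
            "t_decay": self.t_decay,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "SignalProfile":
        doc = dict(doc)
        doc["post_pulse_mode"] = PostPulseMode(doc.get("post_pulse_mode", "sustained"))
        return cls(**doc)


@dataclasses.dataclass(frozen=True)
class ModelParameters:
    """All rate constants of either model, plus the model kind.

    ``k1``/``k2`` are signal-driven transcription rates of *Il6* and
    *Zc3h12a*; ``k3`` the translation rate of *Zc3h12a*; ``d1``/``d2`` the
    free-Regnase-1-induced degradation rates of the two mRNAs;
    ``d1p``/``d2p`` the bound-Regnase-1-induced degradation rates (Model 2
    only, forced to 0 under Model 1); ``d3`` the basal protein turnover;
    ``d4``/``d5`` basal mRNA turnover; ``d6`` the signal-dependent
    (ubiquitin-mediated) protein degradation rate; ``d7`` the
    signal-dependent 14-3-3 binding rate; ``d8`` degradation and ``d9``
    dissociation of the bound complex.  Units: first-order rates in
    hr^-1, the bilinear ``d1``/``d2``/``d1p``/``d2p`` in (conc. hr)^-1.
    """

    kind: ModelKind
    k1: float
    k2: float
    k3: float
    d1: float
    d2: float
    d3: float
    d4: float
    d5: float
    d6: float
    d7: float
    d8: float
    d9: float
    d1p: float = 0.0
    d2p: float = 0.0

    def __post_init__(self) -> None:
        if not isinstance(self.kind, ModelKind):
            object.__setattr__(self, "kind", ModelKind(self.kind))
        for name in RATE_NAMES:
            object.__setattr__(
                self, name, _require_finite_nonneg(name, getattr(self, name))
            )
        if self.kind is ModelKind.MODEL_1 and (self.d1p != 0.0 or self.d2p != 0.0):
            raise ValueError(
                "d1p and d2p are defined only for Model 2; "
                f"got d1p={self.d1p}, d2p={self.d2p} under MODEL_1"
            )

    def replace(self, **changes: object) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def to_dict(self, genotype: Genotype | None = None) -> dict:
        doc = {name: getattr(self, name) for name in RATE_NAMES}
        doc["kind"] = self.kind.value
        if genotype is not None:
            doc["genotype"] = genotype.value
        return doc

    @classmethod
    def from_dict(cls, doc: dict) -> "ModelParameters":
        fields = {name: doc[name] for name in RATE_NAMES}
        return cls(kind=ModelKind(doc["kind"]), **fields)


@dataclasses.dataclass(frozen=True)
class State:
    """Nonnegative abundances (x1, x2, x3, x4).

    x1: *Il6* mRNA; x2: *Zc3h12a* mRNA; x3: free Regnase-1 protein;
    x4: 14-3-3-bound Regnase-1 protein.
    """

    x1: float
    x2: float
    x3: float
    x4: float

    def __post_init__(self) -> None:
        for name in ("x1", "x2", "x3", "x4"):
            object.__setattr__(
                self, name, _require_finite_nonneg(name, getattr(self, name))
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.x1, self.x2, self.x3, self.x4], dtype=float)

    @classmethod
    def from_array(cls, x: Iterable[float]) -> "State":
        x1, x2, x3, x4 = (float(v) for v in x)
        return cls(x1, x2, x3, x4)


def signal_at(profile: SignalProfile, t: float) -> float:
    """Stimulation strength at time ``t`` (hours) under the pulse profile.

    Piecewise: basal, linear ramp, plateau, then post-pulse behaviour set
    by ``profile.post_pulse_mode``.  Continuous in ``t`` in both modes.

    Raises
    ------
    ValueError
        If ``t`` is negative or not finite.
    """
    t = float(t)
    if math.isnan(t) or t < 0:
        raise ValueError(f"time must be nonnegative, got {t!r}")
    t_ramp_start = profile.t_delay
    t_ramp_end = profile.t_delay + profile.t_raise
    t_off = profile.t_pulse_end
    if t <= t_ramp_start:
        return profile.s_base
    if t <= t_ramp_end:
        # zero-length ramp already captured by the branch above
        frac = (t - t_ramp_start) / profile.t_raise
        return profile.s_base + (profile.s_input - profile.s_base) * frac
    if t <= t_off or profile.post_pulse_mode is PostPulseMode.SUSTAINED:
        return profile.s_input
    return profile.s_base + (profile.s_input - profile.s_base) * math.exp(
        -(t - t_off) / profile.t_decay
    )


def apply_genotype(params: ModelParameters, genotype: Genotype) -> ModelParameters:
    """Effective parameters for a genotype.

    WT returns the parameters unchanged; S513A zeroes the 14-3-3
    binding/complex rates d7, d8, d9 (no phosphorylation at S513, hence no
    binding).  Pure: the input is never modified.
    """
    if genotype is Genotype.WT:
        return params
    if genotype is Genotype.S513A:
        return params.replace(d7=0.0, d8=0.0, d9=0.0)
    raise ValueError(f"unknown genotype {genotype!r}")


def _rhs_array(params: ModelParameters, x: np.ndarray, s: float) -> np.ndarray:
    """Unvalidated RHS on a raw 4-array; hot path for the integrator."""
    x1, x2, x3, x4 = x
    p = params
    dx1 = p.k1 * s - p.d1 * x1 * x3 - p.d4 * x1
    dx2 = p.k2 * s - p.d2 * x2 * x3 - p.d5 * x2
    if p.kind is ModelKind.MODEL_2:
        dx1 -= p.d1p * x1 * x4
        dx2 -= p.d2p * x2 * x4
    dx3 = p.k3 * x2 - (p.d3 + p.d6 * s + p.d7 * s) * x3 + p.d9 * x4
    dx4 = p.d7 * s * x3 - (p.d8 + p.d9) * x4
    return np.array([dx1, dx2, dx3, dx4])


def rhs(params: ModelParameters, state: "State | Iterable[float]", s: float) -> np.ndarray:
    """Time derivative (dx1/dt, dx2/dt, dx3/dt, dx4/dt) at a state.

    Model 1 omits the bound-protein degradation terms; Model 2 adds
    ``-d1p*x1*x4`` and ``-d2p*x2*x4`` to the two mRNA equations.

    Raises
    ------
    ValueError
        If any state component or the signal ``s`` is negative.
    """
    x = state.as_array() if isinstance(state, State) else np.asarray(state, dtype=float)
    if x.shape != (4,):
        raise ValueError(f"state must have 4 components, got shape {x.shape}")
    if np.any(x < 0) or np.any(~np.isfinite(x)):
        raise ValueError(f"state components must be finite and nonnegative, got {x}")
    s = float(s)
    if math.isnan(s) or s < 0:
        raise ValueError(f"signal must be nonnegative, got {s!r}")
    return _rhs_array(params, x, s)


# -- flat JSON serialization ------------------------------------------------

def save_params(path, params: ModelParameters, genotype: Genotype = Genotype.WT) -> None:
    """Write a parameter set (plus genotype) as a flat JSON document."""
    with open(path, "w") as fh:
        json.dump(params.to_dict(genotype), fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_params(path) -> tuple[ModelParameters, Genotype]:
    """Read a flat JSON parameter document; returns (params, genotype)."""
    with open(path) as fh:
        doc = json.load(fh)
    genotype = Genotype(doc.get("genotype", "WT"))
    return ModelParameters.from_dict(doc), genotype


def save_profile(path, profile: SignalProfile) -> None:
    with open(path, "w") as fh:
        json.dump(profile.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_profile(path) -> SignalProfile:
    with open(path) as fh:
        return SignalProfile.from_dict(json.load(fh))
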