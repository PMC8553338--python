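"""Packaged default parameter sets and stimulation profile.

The source analysis is purely symbolic and publishes no numeric rate
constants, so these values are illustrative, hand-tuned once so the
noiseless wild-type time course shows the qualitative behaviour the
models were built to explain:

* total Regnase-1 dips below its resting level within ~30 min of pulse
  onset (fast signal-dependent degradation outruns the lagging
  transcription-translation supply) and overshoots it by 4 h;
* total Regnase-1 in S513A cells stays below wild type at late times
  (no protected 14-3-3-bound pool);
* free Regnase-1 and *Il6* mRNA are comparable (within 10%) between the
  genotypes at 4 h under Model 1.

They are NOT estimates of real cellular rates.
"""

from __future__ import annotations

from .core import ModelKind, ModelParameters, PostPulseMode, SignalProfile

__all__ = [
    "default_parameters",
    "default_signal_profile",
    "DEFAULT_MODEL2_D1P",
    "DEFAULT_MODEL2_D2P",
]

#: Bound-Regnase-1 activity used for the Model 2 variant of the defaults.
DEFAULT_MODEL2_D1P = 1.0
DEFAULT_MODEL2_D2P = 1.0

_BASE_RATES = dict(
    k1=1.0,   # Il6 transcription per unit signal (conc/hr)
    k2=1.0,   # Zc3h12a transcription per unit signal (conc/hr)
    k3=1.0,   # Zc3h12a translation (1/hr)
    d1=1.0,   # free-Reg1-induced Il6 mRNA decay (1/(conc*hr))
    d2=1.0,   # free-Reg1-induced Zc3h12a mRNA decay (1/(conc*hr))
    d3=0.05,  # basal Reg1 protein turnover (1/hr): stable when unstimulated
    d4=0.5,   # Reg1-independent Il6 mRNA decay (1/hr)
    d5=1.0,   # Reg1-independent Zc3h12a mRNA decay (1/hr)
    d6=1.5,   # ubiquitin-dependent Reg1 decay per unit signal (1/hr)
    d7=0.5,   # Reg1 -> 14-3-3 binding per unit signal (1/hr)
    d8=0.2,   # decay of 14-3-3-bound Reg1 (1/hr): protected pool
    d9=2.0,   # dissociation from 14-3-3 (1/hr)
)


def default_parameters(kind: ModelKind = ModelKind.MODEL_1) -> ModelParameters:
    """Illustrative rate constants for either model.

    The Model 2 variant keeps the same shared rates and switches on the
    bound-protein mRNA degradation activity (d1p, d2p).
    """
    if kind is ModelKind.MODEL_2:
        return ModelParameters(
            kind=kind, d1p=DEFAULT_MODEL2_D1P, d2p=DEFAULT_MODEL2_D2P, **_BASE_RATES
        )
    return ModelParameters(kind=ModelKind(kind), **_BASE_RATES)


def default_signal_profile() -> SignalProfile:
    """Sustained stimulation: low basal tone, ramp over 15 min after a
    15-min delay, then full-strength signal held through the 4 h window."""
    return SignalProfile(
        s_base=0.05,
        s_input=1.0,
        t_delay=0.25,
        t_raise=0.25,
        t_pulse=3.5,
        post_pulse_mode=PostPulseMode.SUSTAINED,
        t_decay=1.0,
    )
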