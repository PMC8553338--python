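"""Shared builders for randomized parameter draws."""

import numpy as np

from reg1dyn import ModelKind, ModelParameters, RATE_NAMES


def random_params(
    rng: np.random.Generator,
    kind: ModelKind = ModelKind.MODEL_1,
    low: float = 0.1,
    high: float = 2.0,
) -> ModelParameters:
    """Draw every rate constant uniformly from [low, high]."""
    vals = {n: float(rng.uniform(low, high)) for n in RATE_NAMES}
    if kind is ModelKind.MODEL_1:
        vals["d1p"] = vals["d2p"] = 0.0
    return ModelParameters(kind=kind, **vals)


def all_ones(kind: ModelKind = ModelKind.MODEL_1, **overrides) -> ModelParameters:
    """Every rate constant 1 (primed rates 0 under Model 1)."""
    vals = {n: 1.0 for n in RATE_NAMES}
    if kind is ModelKind.MODEL_1:
        vals["d1p"] = vals["d2p"] = 0.0
    vals.update(overrides)
    return ModelParameters(kind=kind, **vals)
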