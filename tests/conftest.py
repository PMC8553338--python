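import numpy as np
import pytest

from reg1dyn import ModelKind, SignalProfile
from reg1dyn.defaults import default_parameters, default_signal_profile

from helpers import all_ones


@pytest.fixture
def ones_params():
    """Model 1 with every rate constant equal to 1."""
    return all_ones(ModelKind.MODEL_1)


@pytest.fixture
def unit_profile():
    """The worked-example pulse: 0.1 basal, ramp to 1 over 15 min."""
    return SignalProfile(s_base=0.1, s_input=1.0, t_delay=0.25, t_raise=0.25, t_pulse=1.0)


@pytest.fixture
def default_params():
    return default_parameters()


@pytest.fixture
def default_profile():
    return default_signal_profile()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
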