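"""Signal function, genotype semantics, right-hand sides, serialization."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reg1dyn import (
    Genotype,
    ModelKind,
    ModelParameters,
    PostPulseMode,
    RATE_NAMES,
    SignalProfile,
    State,
    apply_genotype,
    equilibrium_closed_form,
    load_params,
    load_profile,
    rhs,
    save_params,
    save_profile,
    signal_at,
)

from helpers import all_ones, random_params


class TestSignal:
    @pytest.mark.parametrize(
        "t, expected",
        [
            (0.0, 0.1),            # basal before the delay
            (0.25, 0.1),           # ramp start is still basal
            (0.375, 0.55),         # midpoint of the linear ramp
            (0.5, 1.0),            # plateau start
            (1.0, 1.0),            # on the plateau
            (100.0, 1.0),          # sustained: signal -> s_input for t -> inf
        ],
    )
    def test_piecewise_values(self, unit_profile, t, expected):
        assert signal_at(unit_profile, t) == pytest.approx(expected, abs=1e-12)

    def test_decaying_mode_relaxes_to_basal(self, unit_profile):
        prof = dataclasses.replace(
            unit_profile, post_pulse_mode=PostPulseMode.DECAYING, t_decay=0.5
        )
        t_off = prof.t_pulse_end
        assert signal_at(prof, t_off) == pytest.approx(1.0)
        assert signal_at(prof, t_off + 0.5) == pytest.approx(0.1 + 0.9 / math.e)
        assert signal_at(prof, t_off + 50.0) == pytest.approx(0.1, abs=1e-9)

    def test_negative_time_rejected(self, unit_profile):
        with pytest.raises(ValueError):
            signal_at(unit_profile, -0.1)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        s_base=st.floats(0, 1),
        extra=st.floats(0, 2),
        t_delay=st.floats(0, 2),
        t_raise=st.floats(0, 2),
        t_pulse=st.floats(0, 2),
        mode=st.sampled_from(list(PostPulseMode)),
        t_decay=st.floats(0.1, 5),
    )
    def test_continuity_at_breakpoints(
        self, s_base, extra, t_delay, t_raise, t_pulse, mode, t_decay
    ):
        prof = SignalProfile(
            s_base=s_base, s_input=s_base + extra, t_delay=t_delay,
            t_raise=t_raise, t_pulse=t_pulse, post_pulse_mode=mode, t_decay=t_decay,
        )
        eps = 1e-12
        for bp in (t_delay, t_delay + t_raise, prof.t_pulse_end):
            below = signal_at(prof, max(bp - eps, 0.0))
            above = signal_at(prof, bp + eps)
            assert abs(below - above) < 1e-9

    def test_s_input_below_s_base_rejected(self):
        with pytest.raises(ValueError):
            SignalProfile(s_base=1.0, s_input=0.5)


class TestGenotype:
    def test_s513a_zeroes_binding_rates_only(self):
        p = all_ones(d7=0.3, d8=0.2, d9=0.1)
        q = apply_genotype(p, Genotype.S513A)
        assert (q.d7, q.d8, q.d9) == (0.0, 0.0, 0.0)
        for name in RATE_NAMES:
            if name not in ("d7", "d8", "d9"):
                assert getattr(q, name) == getattr(p, name)
        # pure: the input is untouched
        assert (p.d7, p.d8, p.d9) == (0.3, 0.2, 0.1)

    def test_wt_is_identity(self, ones_params):
        assert apply_genotype(ones_params, Genotype.WT) is ones_params

    def test_idempotent(self, rng):
        p = random_params(rng)
        once = apply_genotype(p, Genotype.S513A)
        assert apply_genotype(once, Genotype.S513A) == once


class TestRhs:
    def test_origin_keeps_only_transcription(self, ones_params):
        np.testing.assert_array_equal(
            rhs(ones_params, State(0, 0, 0, 0), 1.0), [1.0, 1.0, 0.0, 0.0]
        )

    def test_model2_with_zero_primed_rates_reduces_to_model1(self, rng):
        for _ in range(1000):
            vals = {n: float(rng.uniform(0, 2)) for n in RATE_NAMES}
            vals["d1p"] = vals["d2p"] = 0.0
            p1 = ModelParameters(kind=ModelKind.MODEL_1, **vals)
            p2 = ModelParameters(kind=ModelKind.MODEL_2, **vals)
            x = rng.uniform(0, 3, size=4)
            s = float(rng.uniform(0, 2))
            np.testing.assert_array_equal(rhs(p1, x, s), rhs(p2, x, s))

    def test_nonnegative_orthant_is_forward_invariant(self, rng):
        # on each face x_i = 0 the i-th derivative must be >= 0
        for _ in range(200):
            p = random_params(rng, kind=ModelKind.MODEL_2)
            x = rng.uniform(0, 3, size=4)
            s = float(rng.uniform(0, 2))
            for i in range(4):
                face = x.copy()
                face[i] = 0.0
                assert rhs(p, face, s)[i] >= 0.0

    def test_zero_at_closed_form_equilibrium(self, ones_params):
        eq = equilibrium_closed_form(ones_params, Genotype.WT, 1.0)
        res = rhs(ones_params, eq.as_state(), 1.0)
        assert np.max(np.abs(res)) < 1e-10

    def test_negative_inputs_rejected(self, ones_params):
        with pytest.raises(ValueError):
            rhs(ones_params, [-0.1, 0, 0, 0], 1.0)
        with pytest.raises(ValueError):
            rhs(ones_params, [1, 1, 1, 1], -1.0)


class TestValidation:
    def test_model1_forbids_primed_rates(self):
        with pytest.raises(ValueError):
            all_ones(ModelKind.MODEL_1, d1p=0.5)

    @pytest.mark.parametrize("bad", [-1.0, math.nan, math.inf])
    def test_rates_must_be_finite_nonnegative(self, bad):
        with pytest.raises(ValueError):
            all_ones(k1=bad)

    def test_state_rejects_negative_components(self):
        with pytest.raises(ValueError):
            State(1, -1e-3, 0, 0)


class TestSerialization:
    def test_params_round_trip_is_lossless(self, tmp_path, rng):
        p = random_params(rng, kind=ModelKind.MODEL_2)
        path = tmp_path / "params.json"
        save_params(path, p, Genotype.S513A)
        q, genotype = load_params(path)
        assert q == p
        assert genotype is Genotype.S513A

    def test_profile_round_trip_is_lossless(self, tmp_path):
        prof = SignalProfile(
            s_base=0.03, s_input=1.7, t_delay=0.2, t_raise=0.4, t_pulse=2.5,
            post_pulse_mode=PostPulseMode.DECAYING, t_decay=0.8,
        )
        path = tmp_path / "profile.json"
        save_profile(path, prof)
        assert load_profile(path) == prof
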