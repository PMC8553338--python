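"""Closed-form fixed points: existence constant K, both branches, oracle."""

import math

import numpy as np
import pytest

from reg1dyn import (
    ConvergenceError,
    DegenerateParameterError,
    EquilibriumBranch,
    EquilibriumResult,
    Genotype,
    ModelKind,
    State,
    apply_genotype,
    effective_K,
    equilibrium_closed_form,
    equilibrium_numeric_oracle,
    rhs,
    solve_k2_for_target_x3,
)

from helpers import all_ones, random_params


class TestEffectiveK:
    def test_all_ones(self, ones_params):
        # (1/1)*(1 + 1 + 1 - 1/(1+1))
        assert effective_K(ones_params, 1.0) == pytest.approx(2.5, abs=1e-12)

    def test_no_binding_drops_the_fraction(self):
        p = all_ones(d7=0.0, d9=0.7)
        assert effective_K(p, 1.0) == pytest.approx(2.0, abs=1e-12)

    def test_nonnegative_for_nonnegative_rates(self, rng):
        # algebraically d7 s - d7 d9 s/(d8 + d9) = d7 s d8/(d8 + d9) >= 0
        for _ in range(1000):
            p = random_params(rng, low=0.0, high=2.0).replace(k3=float(rng.uniform(0.1, 2)))
            s = float(rng.uniform(0, 2))
            K = effective_K(p, s)
            assert K >= 0.0
            den = p.d8 + p.d9
            identity = p.d3 + p.d6 * s + (0.0 if den == 0 else p.d7 * s * p.d8 / den)
            assert K * p.k3 == pytest.approx(identity, rel=1e-12, abs=1e-12)

    def test_zero_translation_rejected(self, ones_params):
        with pytest.raises(DegenerateParameterError):
            effective_K(ones_params.replace(k3=0.0), 1.0)


class TestClosedForm:
    def test_wt_all_ones(self, ones_params):
        eq = equilibrium_closed_form(ones_params, Genotype.WT, 1.0)
        x3 = (-2.5 + math.sqrt(16.25)) / 5.0  # positive root of 2.5 X^2 + 2.5 X - 1
        assert eq.exists and eq.branch is EquilibriumBranch.WT_GENERAL
        assert eq.X3 == pytest.approx(x3, rel=1e-14)
        assert eq.X4 == pytest.approx(x3 / 2.0, rel=1e-14)
        assert eq.X2 == pytest.approx(2.5 * x3, rel=1e-14)
        assert eq.X1 == pytest.approx(1.0 / (x3 + 1.0), rel=1e-14)

    def test_s513a_all_ones(self, ones_params):
        eq = equilibrium_closed_form(ones_params, Genotype.S513A, 1.0)
        x2 = -1.0 + math.sqrt(3.0)  # positive root of 0.5 X^2 + X - 1
        assert eq.branch is EquilibriumBranch.S513A_REDUCED
        assert eq.X2 == pytest.approx(x2, rel=1e-14)
        assert eq.X3 == pytest.approx(x2 / 2.0, rel=1e-14)
        assert eq.X1 == pytest.approx(1.0 / (x2 / 2.0 + 1.0), rel=1e-14)
        assert eq.X4 == 0.0

    def test_zero_signal_gives_origin(self, rng):
        for kind in ModelKind:
            p = random_params(rng, kind=kind)
            for g in Genotype:
                eq = equilibrium_closed_form(p, g, 0.0)
                assert (eq.X1, eq.X2, eq.X3, eq.X4) == (0.0, 0.0, 0.0, 0.0)

    def test_frozen_complex_pool_rejected(self, ones_params):
        # d8 + d9 = 0 with d7*s > 0: X4 has no finite closed form
        p = ones_params.replace(d8=0.0, d9=0.0)
        with pytest.raises(DegenerateParameterError):
            equilibrium_closed_form(p, Genotype.WT, 1.0)

    def test_no_binding_wt_falls_back_to_reduced_branch(self, ones_params):
        p = ones_params.replace(d7=0.0, d8=0.0, d9=0.0)
        eq = equilibrium_closed_form(p, Genotype.WT, 1.0)
        assert eq.branch is EquilibriumBranch.S513A_REDUCED
        oracle = equilibrium_numeric_oracle(p, Genotype.WT, 1.0, State(1, 1, 1, 1))
        np.testing.assert_allclose(
            eq.as_state().as_array(), oracle.as_array(), rtol=1e-8, atol=1e-10
        )

    def test_residual_vanishes_over_random_draws(self, rng):
        for _ in range(200):
            kind = ModelKind.MODEL_2 if rng.uniform() < 0.5 else ModelKind.MODEL_1
            p = random_params(rng, kind=kind)
            g = Genotype.S513A if rng.uniform() < 0.5 else Genotype.WT
            s = float(rng.uniform(0.1, 2))
            eq = equilibrium_closed_form(p, g, s)
            assert eq.exists
            res = rhs(apply_genotype(p, g), eq.as_state(), s)
            assert np.max(np.abs(res)) < 1e-9
            assert min(eq.X1, eq.X2, eq.X3, eq.X4) >= 0.0

    def test_discarded_quadratic_root_is_negative(self, rng):
        # roots multiply to c/a < 0, so the second root is negative whenever
        # the kept one is positive
        for _ in range(200):
            p = random_params(rng)
            s = float(rng.uniform(0.1, 2))
            K = effective_K(p, s)
            ratio = p.d7 * s / (p.d8 + p.d9)
            a = (p.d2 + ratio * p.d2p) * K
            b = p.d5 * K
            c = -p.k2 * s
            kept = equilibrium_closed_form(p, Genotype.WT, s).X3
            other = (-b - math.sqrt(b * b - 4 * a * c)) / (2 * a)
            assert kept > 0 > other
            assert a * kept**2 + b * kept + c == pytest.approx(0.0, abs=1e-10)

    def test_nonexistent_result_has_no_state(self):
        bad = EquilibriumResult(
            math.nan, math.nan, math.nan, math.nan,
            K=-1.0, exists=False, branch=EquilibriumBranch.WT_GENERAL,
        )
        with pytest.raises(ValueError):
            bad.as_state()


class TestNumericOracle:
    @pytest.mark.parametrize("kind", list(ModelKind))
    @pytest.mark.parametrize("genotype", list(Genotype))
    def test_matches_closed_form(self, rng, kind, genotype):
        for _ in range(50):
            p = random_params(rng, kind=kind)
            s = float(rng.uniform(0.1, 2))
            eq = equilibrium_closed_form(p, genotype, s)
            root = equilibrium_numeric_oracle(p, genotype, s, State(1, 1, 1, 1))
            np.testing.assert_allclose(
                root.as_array(), eq.as_state().as_array(), rtol=1e-8, atol=1e-10
            )

    def test_origin_root_at_zero_signal(self, ones_params):
        root = equilibrium_numeric_oracle(ones_params, Genotype.WT, 0.0, State(0, 0, 0, 0))
        assert np.max(root.as_array()) < 1e-10

    def test_nonconvergence_is_reported(self, ones_params):
        with pytest.raises(ConvergenceError):
            equilibrium_numeric_oracle(
                ones_params, Genotype.WT, 1.0, State(1, 1, 1, 1), residual_tol=1e-30
            )


class TestSolveK2:
    def test_inverts_the_all_ones_s513a_example(self, ones_params):
        target = (-1.0 + math.sqrt(3.0)) / 2.0
        k2 = solve_k2_for_target_x3(ones_params, Genotype.S513A, 1.0, target)
        assert k2 == pytest.approx(1.0, rel=1e-12)

    def test_wt_direct_evaluation(self, ones_params):
        # 2.5*0.25 + 2.5*0.5 = 1.875
        k2 = solve_k2_for_target_x3(ones_params, Genotype.WT, 1.0, 0.5)
        assert k2 == pytest.approx(1.875, rel=1e-14)

    def test_zero_target_needs_no_transcription(self, ones_params):
        assert solve_k2_for_target_x3(ones_params, Genotype.WT, 1.0, 0.0) == 0.0

    def test_negative_target_rejected(self, ones_params):
        with pytest.raises(ValueError):
            solve_k2_for_target_x3(ones_params, Genotype.WT, 1.0, -0.1)

    @pytest.mark.parametrize("genotype", list(Genotype))
    def test_round_trip_recovers_the_target(self, rng, genotype):
        for _ in range(100):
            p = random_params(rng, kind=ModelKind.MODEL_2)
            s = float(rng.uniform(0.1, 2))
            target = float(rng.uniform(0.0, 2))
            k2 = solve_k2_for_target_x3(p, genotype, s, target)
            eq = equilibrium_closed_form(p.replace(k2=k2), genotype, s)
            assert abs(eq.X3 - target) < 1e-10
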