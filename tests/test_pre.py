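"""Pre-telemedicine equilibrium: cutoffs, regimes, and the GP's referral choice."""

import numpy as np
import pytest

from telerefer import (cutoff_direct_vs_gp, gp_profit_pre, optimize_gp_referral,
                       solve_full_coverage, solve_partial_coverage,
                       solve_pre_equilibrium, utilities_pre)
from telerefer.oracle import iterate_pre
from telerefer.pre import (DegenerateReferralError, RegimeMismatchError,
                           best_response_gain_pre)
from tests.conftest import draw_params


class TestUtilities:
    def test_direct_specialist_at_origin(self, ex_params):
        us, _ = utilities_pre(0.5, 0.0, 6.0, ex_params)
        assert us == pytest.approx(11.0)   # 20 - 3 - 6 - 0

    def test_gp_first_evaluation(self, ex_params):
        _, ug = utilities_pre(0.5, 1.0, 6.0, ex_params)
        assert ug == pytest.approx(5.125)  # 3.75 - 0.5 - 1.25 + 0.625*5

    def test_vanishing_referral_is_pure_passthrough(self, ex_params):
        # with F(k) ~ 0 the GP cures nobody and charges almost nothing
        us, ug = utilities_pre(1e-9, 0.3, 6.0, ex_params)
        assert ug == pytest.approx(us, abs=1e-7)


class TestCutoff:
    def test_example_value(self, ex_params):
        d_hat = cutoff_direct_vs_gp(0.5, 6.0, ex_params, upper=10.0)
        assert d_hat == pytest.approx(2.4444444444 + (20 - 10 - 10 - 3 - 6) / 6, abs=1e-9)
        assert d_hat == pytest.approx(0.944444444444, abs=1e-9)

    def test_indifference_at_interior_cutoff(self, ex_params):
        d_hat = cutoff_direct_vs_gp(0.5, 6.0, ex_params, upper=10.0)
        us, ug = utilities_pre(0.5, d_hat, 6.0, ex_params)
        assert abs(us - ug) < 1e-8

    def test_large_quality_cost_clamps_to_zero(self, ex_params):
        assert cutoff_direct_vs_gp(0.5, 1e3, ex_params) == 0.0

    def test_degenerate_referral_raises(self, ex_params):
        with pytest.raises(DegenerateReferralError):
            cutoff_direct_vs_gp(0.0, 6.0, ex_params)


class TestFullCoverage:
    def test_frozen_example(self, ex_params):
        st = solve_full_coverage(0.5, ex_params)
        assert st.d_hat == pytest.approx(0.9506172839506, abs=1e-9)
        assert st.lam_s == pytest.approx(0.9814814814815, abs=1e-9)
        assert st.mu == pytest.approx(1.9814814814815, abs=1e-9)
        assert st.diagnostics["cutoff_residual"] < 1e-9

    def test_marginal_patient_still_gains(self, ex_params):
        st = solve_full_coverage(0.5, ex_params)
        us_far, _ = utilities_pre(0.5, ex_params.dmax, st.qc, ex_params)
        assert us_far == pytest.approx(5.037, abs=1e-3)
        assert us_far >= 0

    def test_tiny_referral_sends_everyone_to_specialist(self, ex_params):
        # with F(k) ~ 0 the GP cures nobody, so the whole market reaches the SP
        st = solve_full_coverage(1e-4, ex_params)
        assert st.lam_s == pytest.approx(ex_params.dmax, rel=1e-3)


class TestPartialCoverage:
    def test_frozen_example(self, ex_params3):
        st = solve_partial_coverage(0.5, ex_params3)
        assert st.d_hat == pytest.approx(0.8194444444444, abs=1e-9)
        assert st.d_o == pytest.approx(1.7083333333333, abs=1e-9)
        assert st.lam_s == pytest.approx(1.375, abs=1e-9)
        assert st.mu == pytest.approx(2.375, abs=1e-9)

    def test_zero_utility_at_giveup_boundary(self, ex_params3):
        st = solve_partial_coverage(0.5, ex_params3)
        us, _ = utilities_pre(0.5, st.d_o, st.qc, ex_params3)
        assert abs(us) < 1e-8

    def test_giveup_mass(self, ex_params3):
        st = solve_partial_coverage(0.5, ex_params3)
        assert ex_params3.dmax - st.d_o == pytest.approx(1.2916666667, abs=1e-9)

    def test_regime_mismatch_on_small_market(self, ex_params):
        with pytest.raises(RegimeMismatchError):
            solve_partial_coverage(0.5, ex_params)   # dmax=1 is fully covered


class TestGPProfit:
    def test_zero_referral_zero_profit(self, ex_params):
        assert gp_profit_pre(0.0, 0.3, ex_params) == 0.0

    def test_example_composition(self, ex_params):
        st = solve_full_coverage(0.5, ex_params)
        pi = gp_profit_pre(0.5, st.d_hat, ex_params)
        assert pi == pytest.approx((1 - 0.9506172839506) * (6 * 0.5 - 10 * 0.125), abs=1e-9)
        assert pi == pytest.approx(0.0864, abs=1e-3)

    def test_mistreatment_can_turn_profit_negative(self, ex_params):
        # (Pg - Cg)k < m(k - F(k)) at high k with a large mistreatment cost
        p = ex_params.replace(m=15.0, Pg=10.0, Cg=6.0)
        assert gp_profit_pre(1.0, 0.2, p) < 0


class TestReferralOptimization:
    @pytest.mark.parametrize("solver", [solve_full_coverage,
                                        lambda k, p: solve_partial_coverage(k, p, strict=False)])
    def test_matches_brute_force_grid(self, ex_params3, solver):
        k_star = optimize_gp_referral(ex_params3, solver, grid_n=401)
        ks = np.linspace(1e-4, 1.0, 2001)
        vals = [solver(float(k), ex_params3).pi_g for k in ks]
        k_grid = float(ks[int(np.argmax(vals))])
        assert k_star == pytest.approx(k_grid, abs=1e-3)
        assert solver(k_star, ex_params3).pi_g >= max(vals) - 1e-9


class TestEquilibrium:
    def test_small_market_is_fully_covered(self, ex_params):
        st = solve_pre_equilibrium(ex_params)
        assert st.regime == "full"

    def test_large_market_is_partially_covered(self, ex_params3):
        st = solve_pre_equilibrium(ex_params3)
        assert st.regime == "partial"
        assert st.d_o < ex_params3.dmax

    def test_cheap_travel_restores_full_coverage(self, ex_params3):
        st = solve_pre_equilibrium(ex_params3.replace(Ct=0.5))
        assert st.regime == "full"

    def test_invariants_and_oracle_agreement_on_random_draws(self):
        """Masses conserve, indifference holds, and damped iteration agrees."""
        rng = np.random.default_rng(7)
        for _ in range(5):
            p = draw_params(rng, dmax=float(rng.choice([1.0, 2.0])))
            st = solve_pre_equilibrium(p)
            assert 0.0 <= st.d_hat <= st.d_o <= p.dmax + 1e-12
            assert st.mu > st.lam_s
            F = p.success().F(st.k)
            assert st.lam_s == pytest.approx(
                st.d_hat + (st.d_o - st.d_hat) * (1 - F), abs=1e-9)
            assert abs(p.beta / (st.mu - st.lam_s) ** 2 - p.alpha) < 1e-9
            if not st.clamped and st.d_hat > 1e-9:
                us, ug = utilities_pre(st.k, st.d_hat, st.qc, p)
                assert abs(us - ug) < 1e-8
            it = iterate_pre(st.k, p)
            assert it["regime"] == st.regime
            assert it["d_hat"] == pytest.approx(st.d_hat, abs=1e-3 * p.dmax)
            assert it["lam_s"] == pytest.approx(st.lam_s, abs=1e-3 * p.dmax)
            assert best_response_gain_pre(st, p) < 1e-6
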