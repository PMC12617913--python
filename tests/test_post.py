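"""Post-telemedicine equilibrium: tele cutoff, scenarios, mixed strategies."""

import numpy as np
import pytest

from telerefer import (gp_profit_post, indifference_target, solve_post_at_k,
                       solve_post_equilibrium, solve_pre_equilibrium,
                       solve_scenario1, solve_scenario2, tele_cutoff,
                       utilities_post)
from telerefer.experiments import FULL_DMAX, PARTIAL_DMAX, baseline_params
from telerefer.oracle import iterate_post
from telerefer.post import ScenarioMismatchError, best_response_gain_post


class TestTeleCutoff:
    def test_example_value(self, ex_params):
        # (Rs - Rt + (qs - qt) Ps) / Ct = (5 - 0.75) / 6
        assert tele_cutoff(ex_params) == pytest.approx(0.7083333333333, abs=1e-9)

    def test_vanishes_when_tele_matches_in_person(self, ex_params):
        p = ex_params.replace(Rt=20.0 - 1e-9, qt=0.8 + 1e-9, qg=0.9)
        assert tele_cutoff(p) == pytest.approx(0.0, abs=1e-6)

    def test_decreasing_in_travel_cost(self, ex_params):
        cuts = [tele_cutoff(ex_params.replace(Ct=ct)) for ct in (6.0, 7.0, 8.0)]
        assert cuts == sorted(cuts, reverse=True)


class TestUtilities:
    def test_tele_utility_is_distance_free(self, ex_params):
        _, us2a, _, ug2a = utilities_post(0.5, 0.0, 6.0, ex_params)
        _, us2b, _, ug2b = utilities_post(0.5, 2.0, 6.0, ex_params)
        assert us2a == us2b and ug2a == ug2b
        assert us2a == pytest.approx(6.75)   # 15 - 2.25 - 6

    def test_paths_tie_at_tele_cutoff(self, ex_params):
        d = tele_cutoff(ex_params)
        us1, us2, _, _ = utilities_post(0.5, d, 6.0, ex_params)
        assert us1 == pytest.approx(us2, abs=1e-12)


class TestScenario1:
    def test_frozen_example(self, ex_params3):
        st = solve_scenario1(0.5, ex_params3)
        assert st.d_hat == pytest.approx(0.5802469135802, abs=1e-9)
        assert st.lam_s == pytest.approx(2.0925925925926, abs=1e-9)
        assert st.mu == pytest.approx(3.0925925925926, abs=1e-9)
        assert st.d_hat <= st.d_tilde

    def test_mismatch_raises_when_tele_cutoff_binds(self, ex_params3):
        # near-identical tele reward pushes d_tilde toward 0
        p = ex_params3.replace(Rt=19.9, qt=0.801)
        with pytest.raises(ScenarioMismatchError):
            solve_scenario1(0.5, p)


class TestIndifferenceTarget:
    def test_example_value(self, ex_params3):
        assert indifference_target(0.5, ex_params3) == pytest.approx(5.3333333333, abs=1e-9)

    def test_equals_gp_reward_when_gp_visit_is_free(self, ex_params):
        p = ex_params.replace(qg=1.0, m=1e-12)
        assert indifference_target(0.5, p) == pytest.approx(p.Rg, abs=1e-9)

    def test_decreasing_in_mistreatment_cost(self, ex_params):
        t = [indifference_target(0.5, ex_params.replace(m=m)) for m in (10.0, 12.0, 15.0)]
        assert t == sorted(t, reverse=True)

    def test_consistency_with_utility_functions(self, ex_params3):
        """Ug2 = Us2 exactly when Us2 sits at the target level."""
        target = indifference_target(0.5, ex_params3)
        qc = ex_params3.Rt - (1 - ex_params3.qt) * ex_params3.Ps - target
        _, us2, _, ug2 = utilities_post(0.5, 1.0, qc, ex_params3)
        assert us2 == pytest.approx(target, abs=1e-12)
        assert ug2 == pytest.approx(us2, abs=1e-9)


class TestScenario2:
    def test_clamped_example(self, ex_params3):
        # Rt=19 makes telemedicine so attractive the unconstrained root
        # (~4.85) exceeds the eligible mass; everyone beyond d_tilde goes tele
        p = ex_params3.replace(Rt=19.0)
        st = solve_scenario2(0.5, p)
        assert st.clamped
        assert st.lam_tele == pytest.approx(p.dmax - st.d_tilde, abs=1e-12)
        assert st.lam_tele == pytest.approx(2.9583333333, abs=1e-9)
        assert st.lam_g == pytest.approx(0.0, abs=1e-12)
        # at the boundary, direct telemedicine is strictly preferred
        us2 = p.Rt - (1 - p.qt) * p.Ps - st.qc
        assert us2 > indifference_target(0.5, p)

    def test_interior_indifference(self, ex_params3):
        p = ex_params3.replace(Rt=17.0)
        st = solve_scenario2(0.5, p)
        assert not st.clamped
        assert 0.0 < st.lam_tele < p.dmax - st.d_tilde
        us2 = p.Rt - (1 - p.qt) * p.Ps - st.qc
        assert abs(us2 - indifference_target(0.5, p)) < 1e-8

    def test_matches_bisection_oracle(self, ex_params3):
        p = ex_params3.replace(Rt=17.0)
        st = solve_scenario2(0.5, p)
        it = iterate_post(0.5, p)
        assert it["scenario"] == 2
        assert it["lam_tele"] == pytest.approx(st.lam_tele, abs=1e-6)


class TestGPProfit:
    def test_tiny_tele_reward_recovers_pre_form(self, ex_params3):
        p = ex_params3.replace(gamma=1e-12)
        st = solve_scenario1(0.5, p)
        margin = (p.Pg - p.Cg) * 0.5 - p.m * (0.5 - 0.375)
        assert gp_profit_post(0.5, st, p) == pytest.approx(
            (p.dmax - st.d_hat) * margin, abs=1e-9)

    def test_frozen_scenario1_example(self, ex_params3):
        st = solve_scenario1(0.5, ex_params3)
        assert st.pi_g == pytest.approx(7.0991512346, abs=1e-6)

    def test_pure_assistance_when_everyone_goes_tele(self, ex_params3):
        p = ex_params3.replace(Rt=19.0)
        st = solve_scenario2(0.5, p)
        assert st.pi_g == pytest.approx(p.gamma * st.lam_tele, abs=1e-12)


class TestEquilibrium:
    def test_baseline_is_scenario1(self, ex_params3):
        st = solve_post_equilibrium(ex_params3)
        assert st.scenario == 1
        assert st.d_hat <= st.d_tilde

    def test_attractive_tele_forces_scenario2(self, ex_params3):
        st = solve_post_equilibrium(ex_params3.replace(Rt=19.5, qt=0.805))
        assert st.scenario == 2
        assert st.lam_tele > 0

    def test_scenario_classification_exclusive(self, ex_params3):
        """At any k exactly one scenario is consistent (or scenario 2 clamps)."""
        for k in (0.1, 0.3, 0.5, 0.7, 0.9):
            st = solve_post_at_k(k, ex_params3)
            if st.scenario == 1:
                assert st.d_hat <= st.d_tilde + 1e-9
            else:
                assert st.diagnostics["d_hat_implied"] > st.d_tilde - 1e-9

    def test_no_profitable_patient_deviation(self, ex_params3):
        st = solve_post_equilibrium(ex_params3)
        assert best_response_gain_post(st, ex_params3) < 1e-6

    def test_segment_masses_conserve(self, ex_params3):
        for rt in (15.0, 17.0, 19.0):
            st = solve_post_at_k(0.5, ex_params3.replace(Rt=rt))
            if st.scenario == 1:
                total = st.d_hat + (st.d_tilde - st.d_hat) + (ex_params3.dmax - st.d_tilde)
            else:
                total = st.d_tilde + st.lam_tele + st.lam_g
            assert total == pytest.approx(ex_params3.dmax, abs=1e-9)

    def test_telemedicine_lowers_referral_and_speeds_specialist(self):
        """At the study baselines the GP refers more (k falls) and mu rises."""
        for dmax in (FULL_DMAX, PARTIAL_DMAX):
            p = baseline_params(dmax=dmax)
            pre = solve_pre_equilibrium(p)
            post = solve_post_equilibrium(p)
            assert post.k < pre.k
            assert post.mu > pre.mu
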