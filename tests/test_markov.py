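import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nivoi import markov
from nivoi.markov import (
    DEATH,
    MILD_PTS,
    NO_PTS,
    SEVERE_PTS,
    STRATEGIES,
    CohortTrace,
    CyclePayoffs,
    apply_rr,
    build_payoffs,
    build_transitions,
    cycle_death_probs,
    discounted_ce,
    evaluate_strategies,
    interval_probs_from_cumulative,
    run_ce,
    run_cohort,
)


class TestIntervalProbs:
    def test_case_values(self):
        q1, q2, q3 = interval_probs_from_cumulative(0.211, 0.222, 0.245)
        assert q1 == pytest.approx(0.211)
        assert q2 == pytest.approx(0.013942, abs=1e-6)
        assert q3 == pytest.approx(0.029563, abs=1e-6)
        # recomposition returns the 24-month cumulative exactly
        assert 1 - (1 - q1) * (1 - q2) * (1 - q3) == pytest.approx(0.245, abs=1e-14)

    def test_zero_incidence(self):
        assert interval_probs_from_cumulative(0.0, 0.0, 0.0) == (0.0, 0.0, 0.0)

    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError):
            interval_probs_from_cumulative(0.3, 0.2, 0.4)

    @given(
        c6=st.floats(0.0, 0.8),
        d1=st.floats(0.0, 0.1),
        d2=st.floats(0.0, 0.1),
    )
    def test_recomposition_round_trip(self, c6, d1, d2):
        c12, c24 = c6 + d1, c6 + d1 + d2
        q1, q2, q3 = interval_probs_from_cumulative(c6, c12, c24)
        assert 1 - (1 - q1) * (1 - q2) * (1 - q3) == pytest.approx(c24, abs=1e-12)


class TestApplyRR:
    def test_identity_at_rr_one(self):
        assert apply_rr(0.013942, 0.029563, 1.0) == (0.013942, 0.029563)

    def test_upper_ci_reproduces_margin_increase(self):
        # RR at the prior's 97.5% quantile lifts the 24-month incidence from
        # 24.5% to ~32%, i.e. the 7.5-point margin the design allows
        q1, q2, q3 = interval_probs_from_cumulative(0.211, 0.222, 0.245)
        q2p, q3p = apply_rr(q2, q3, 3.316)
        c24 = 1 - (1 - q1) * (1 - q2p) * (1 - q3p)
        assert c24 == pytest.approx(0.320, abs=0.005)

    def test_clamped_at_one(self):
        assert apply_rr(0.9, 0.9, 3.316) == (1.0, 1.0)

    def test_rr_below_one_rejected(self):
        with pytest.raises(ValueError):
            apply_rr(0.01, 0.01, 0.5)


class TestTransitions:
    def test_death_row_absorbing(self, config, theta_means):
        for cycle in (0, 1, 5, 40):
            t = build_transitions(config, theta_means, STRATEGIES[0], cycle)
            assert np.allclose(t[DEATH], [0, 0, 0, 1])

    def test_rows_sum_to_one(self, config, theta_means):
        for strategy in STRATEGIES:
            for cycle in range(len(config.cycle_plan)):
                t = build_transitions(config, theta_means, strategy, cycle)
                assert np.allclose(t.sum(axis=-1), 1.0, atol=1e-12)

    def test_identity_without_mortality_or_incidence(self, no_mortality_config):
        theta = {"q1": 0.0, "q2": 0.0, "q3": 0.0, "rr_tailored": 1.0}
        t = build_transitions(no_mortality_config, theta, STRATEGIES[0], 0)
        assert np.allclose(t, np.eye(4))

    def test_first_cycle_exit_split(self, config, theta_means):
        t = build_transitions(config, theta_means, STRATEGIES[0], 0)
        d = cycle_death_probs(config)[0]
        exit_to_pts = t[NO_PTS, MILD_PTS] + t[NO_PTS, SEVERE_PTS]
        assert exit_to_pts == pytest.approx(0.211 * (1 - d), rel=1e-12)
        assert t[NO_PTS, MILD_PTS] / exit_to_pts == pytest.approx(0.8)

    def test_no_onset_after_two_years(self, config, theta_means):
        for cycle in (3, 10, 40):
            t = build_transitions(config, theta_means, STRATEGIES[1], cycle)
            assert t[NO_PTS, MILD_PTS] == 0.0
            assert t[NO_PTS, SEVERE_PTS] == 0.0


class TestCohort:
    def test_conservation_and_monotone_death(self, config, theta_means):
        for strategy in STRATEGIES:
            trace = run_cohort(config, theta_means, strategy)
            assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-12)
            assert (np.diff(trace.occupancy[:, DEATH]) >= -1e-15).all()
            assert ((trace.occupancy >= -1e-15) & (trace.occupancy <= 1 + 1e-15)).all()

    def test_all_mass_stays_without_incidence_or_mortality(self, no_mortality_config):
        theta = {"q1": 0.0, "q2": 0.0, "q3": 0.0, "rr_tailored": 1.0}
        trace = run_cohort(no_mortality_config, theta, STRATEGIES[0])
        assert np.allclose(trace.occupancy[:, NO_PTS], 1.0)

    def test_three_cycle_hand_oracle(self, config, theta_means):
        """First three cycles equal explicit hand-computed matrix products."""
        d = cycle_death_probs(config)
        split = config.severity_split_mild
        occ = np.array([1.0, 0.0, 0.0, 0.0])
        expected = [occ.copy()]
        for cyc, q in enumerate((theta_means["q1"], theta_means["q2"], theta_means["q3"])):
            surv = 1 - d[cyc]
            t = np.array([
                [surv * (1 - q), surv * q * split, surv * q * (1 - split), d[cyc]],
                [0.0, surv, 0.0, d[cyc]],
                [0.0, 0.0, surv, d[cyc]],
                [0.0, 0.0, 0.0, 1.0],
            ])
            occ = occ @ t
            expected.append(occ.copy())
        trace = run_cohort(config, theta_means, STRATEGIES[0])
        assert np.allclose(trace.occupancy[:4], np.array(expected), atol=1e-14)

    def test_two_year_pts_prevalence_near_cumulative_incidence(
        self, config, no_mortality_config, theta_means
    ):
        # without mortality the 24-month PTS prevalence is the cumulative
        # incidence exactly; with mortality it is slightly below
        trace0 = run_cohort(no_mortality_config, theta_means, STRATEGIES[0])
        pts0 = trace0.occupancy[3, MILD_PTS] + trace0.occupancy[3, SEVERE_PTS]
        assert pts0 == pytest.approx(0.245, abs=1e-12)
        trace = run_cohort(config, theta_means, STRATEGIES[0])
        pts = trace.occupancy[3, MILD_PTS] + trace.occupancy[3, SEVERE_PTS]
        assert 0.22 < pts < 0.245


class TestDiscountedCE:
    def test_undiscounted_full_health_gives_horizon_qalys(self, no_mortality_config):
        cfg = dataclasses.replace(
            no_mortality_config, max_age=no_mortality_config.start_age + 10,
            discount_cost=0.0, discount_effect=0.0,
            utility_norm_base=1.0, utility_norm_slope=0.0,
        )
        theta = {
            "q1": 0.0, "q2": 0.0, "q3": 0.0, "rr_tailored": 1.0,
            "disutility_mild_pts": 0.0, "disutility_severe_pts": 0.0,
            "disutility_ecs": 0.0, "cost_mild_pts": 0.0, "cost_severe_pts": 0.0,
            "homecare_fraction": 0.0,
        }
        ce = run_ce(cfg, theta, STRATEGIES[0])
        assert ce.qaly == pytest.approx(10.0, abs=1e-12)

    def test_single_cost_at_one_year_discounts_to_present_value(self, config):
        n = len(config.cycle_plan)
        occ = np.zeros((n + 1, 4))
        occ[:, NO_PTS] = 1.0
        trace = CohortTrace(
            occupancy=occ, cycle_lengths=np.asarray(config.cycle_plan),
            start_times=config.cycle_start_times,
            start_ages=config.start_age + config.cycle_start_times,
        )
        cost_rate = np.zeros((n, 4))
        cost_rate[2, NO_PTS] = 100.0  # cycle starting at t = 1 year, length 1
        payoffs = CyclePayoffs(cost_rate=cost_rate, utility_rate=np.zeros((n, 4)))
        ce = discounted_ce(trace, payoffs, config)
        assert ce.cost == pytest.approx(100.0 / 1.04, rel=1e-12)

    def test_strategy_equivalence_when_arms_identical(self, config, theta_means):
        # RR = 1 and no early stopping: the strategies are the same therapy
        cfg = dataclasses.replace(config, stop_fraction_6mo=0.0)
        ce_std = run_ce(cfg, theta_means, STRATEGIES[0])
        ce_tlr = run_ce(cfg, theta_means, STRATEGIES[1])
        assert ce_std.cost == pytest.approx(ce_tlr.cost, rel=1e-14)
        assert ce_std.qaly == pytest.approx(ce_tlr.qaly, rel=1e-14)

    def test_rr_monotonicity_for_tailored_arm(self, config, theta_means):
        qalys, costs = [], []
        for rr in (1.0, 1.5, 2.0, 3.3):
            ce = run_ce(config, {**theta_means, "rr_tailored": rr}, STRATEGIES[1])
            qalys.append(ce.qaly)
            costs.append(ce.cost)
        assert all(a >= b for a, b in zip(qalys, qalys[1:]))
        assert all(a <= b for a, b in zip(costs, costs[1:]))

    def test_case_strategies_differ_modestly_at_prior_means(self, config, theta_means):
        ce_std = run_ce(config, theta_means, STRATEGIES[0])
        ce_tlr = run_ce(config, theta_means, STRATEGIES[1])
        assert abs(ce_std.cost - ce_tlr.cost) < 1000.0
        assert abs(ce_std.qaly - ce_tlr.qaly) < 0.05
        assert 0 < ce_std.cost and 0 < ce_std.qaly <= config.horizon

    def test_negative_utility_clamped_with_warning(self, config):
        cfg = dataclasses.replace(config, utility_norm_base=0.10)
        theta = {
            "q1": 0.3, "q2": 0.1, "q3": 0.1, "rr_tailored": 1.0,
            "disutility_mild_pts": 0.117, "disutility_severe_pts": 0.218,
            "disutility_ecs": 0.02, "cost_mild_pts": 2000.0,
            "cost_severe_pts": 7000.0, "homecare_fraction": 0.075,
        }
        with pytest.warns(RuntimeWarning, match="clamped"):
            ce = run_ce(cfg, theta, STRATEGIES[0])
        assert ce.qaly >= 0.0


class TestBatchConsistency:
    def test_single_draw_matches_batch(self, config, theta_means):
        costs, qalys = evaluate_strategies(config, {k: [v] for k, v in theta_means.items()})
        for j, strategy in enumerate(STRATEGIES):
            ce = run_ce(config, theta_means, strategy)
            assert costs[0, j] == pytest.approx(ce.cost, rel=1e-12)
            assert qalys[0, j] == pytest.approx(ce.qaly, rel=1e-12)

    def test_batch_shapes(self, config, specs):
        from nivoi.params import sample_priors

        draws = sample_priors(specs, 64, seed=3)
        costs, qalys = evaluate_strategies(config, draws)
        assert costs.shape == qalys.shape == (64, 2)
        assert (costs >= 0).all()
        assert (qalys >= 0).all() and (qalys <= config.horizon).all()
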