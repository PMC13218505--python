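import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lipidcea.calibration import rate_to_prob
from lipidcea.markov import (ALIVE, DEAD, HealthState, LifeTable, ArmSpec,
                             N_STATES, discount_factor, make_arms,
                             mortality_split, run_cohort, transition_matrix)
from lipidcea.params import UncertainParam, ValidationError, default_parameters
from lipidcea.sensitivity import _with_value


def _fixed(x):
    return UncertainParam(x, x, x, "fixed")


def zero_event_params(params, utility=0.8, horizon=10, discount=0.0):
    b = params.baseline
    p = dataclasses.replace(params, baseline=dataclasses.replace(
        b, composite=_fixed(0.0), mi=_fixed(0.0), is_=_fixed(0.0),
        cv_death=_fixed(0.0)))
    u = p.utilities
    p = dataclasses.replace(p, utilities=dataclasses.replace(
        u, baseline_ascvd=UncertainParam(utility, utility, utility, "beta")))
    return dataclasses.replace(p, settings=dataclasses.replace(
        p.settings, horizon_years=horizon, discount_rate=discount))


class TestLifeTable:
    def test_rejects_nonincreasing_ages(self):
        with pytest.raises(ValidationError):
            LifeTable(np.array([60.0, 60.0]), np.array([0.01, 0.01]),
                      np.array([0.0, 0.0]))

    def test_rejects_cv_above_all_cause(self):
        with pytest.raises(ValidationError):
            LifeTable(np.array([60.0]), np.array([0.01]), np.array([0.02]))

    def test_age_lookup_uses_floor(self, flat_table):
        assert flat_table.rates_at(59.5) == flat_table.rates_at(59.0)

    def test_age_outside_coverage(self, flat_table):
        with pytest.raises(ValidationError):
            flat_table.rates_at(150.0)

    def test_csv_round_trip(self, life_table, tmp_path):
        path = tmp_path / "lt.csv"
        life_table.to_csv(path)
        back = LifeTable.from_csv(path)
        np.testing.assert_allclose(back.ages, life_table.ages)
        np.testing.assert_allclose(back.all_cause_rate, life_table.all_cause_rate)
        np.testing.assert_allclose(back.cv_rate, life_table.cv_rate)

    def test_csv_missing_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("age,all_cause_rate\n60,0.01\n")
        with pytest.raises(ValidationError, match="cv_rate"):
            LifeTable.from_csv(path)


class TestMortalitySplit:
    def test_subtraction(self, flat_table):
        cv, non_cv = mortality_split(flat_table, 60)
        assert cv == pytest.approx(0.008)
        assert non_cv == pytest.approx(0.012)

    def test_zero_cv(self, zero_mortality_table):
        cv, non_cv = mortality_split(zero_mortality_table, 60)
        assert cv == 0 and non_cv == 0

    def test_conservation_on_synthetic_table(self, life_table):
        for age in life_table.ages:
            cv, non_cv = mortality_split(life_table, age)
            all_cause, _ = life_table.rates_at(age)
            assert cv + non_cv == pytest.approx(all_cause, abs=1e-15)


class TestDiscountFactor:
    def test_zero_rate(self):
        assert all(discount_factor(0.0, k, True) == 1 for k in range(1, 31))

    def test_full_cycle(self):
        assert discount_factor(0.045, 1, False) == pytest.approx(1 / 1.045, abs=1e-15)

    def test_half_cycle(self):
        assert discount_factor(0.045, 1, True) == pytest.approx(1.045 ** -0.5, abs=1e-15)

    def test_invalid_cycle(self):
        with pytest.raises(ValidationError):
            discount_factor(0.045, 0, True)


class TestTransitionMatrix:
    def test_no_risk_matrix(self, params, zero_mortality_table):
        # with zero rates every state is retained, except the acute states,
        # which deterministically feed their post state
        p = zero_event_params(params)
        comparator, _ = make_arms(p)
        m = transition_matrix(p, comparator, zero_mortality_table, 60)
        expected = np.eye(N_STATES)
        expected[HealthState.ACUTE_MI, HealthState.ACUTE_MI] = 0
        expected[HealthState.ACUTE_MI, HealthState.POST_MI] = 1
        expected[HealthState.ACUTE_IS, HealthState.ACUTE_IS] = 0
        expected[HealthState.ACUTE_IS, HealthState.POST_IS] = 1
        np.testing.assert_allclose(m, expected, atol=1e-15)

    def test_rows_sum_to_one(self, params, life_table):
        for arm in make_arms(params):
            for age in (59.5, 70, 85):
                m = transition_matrix(params, arm, life_table, age)
                np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-12)

    def test_baseline_row_matches_eq2_of_table_rates(self, params, zero_mortality_table):
        comparator, _ = make_arms(params)
        m = transition_matrix(params, comparator, zero_mortality_table, 60)
        row = m[HealthState.BASELINE_ASCVD]
        assert row[HealthState.ACUTE_MI] == pytest.approx(rate_to_prob(0.0353), abs=1e-12)
        assert row[HealthState.ACUTE_IS] == pytest.approx(rate_to_prob(0.0172), abs=1e-12)
        assert row[HealthState.DEAD_CV] == pytest.approx(rate_to_prob(0.0070), abs=1e-12)

    def test_treatment_lowers_event_probabilities(self, params, life_table):
        comparator, intervention = make_arms(params)
        m0 = transition_matrix(params, comparator, life_table, 60)
        m1 = transition_matrix(params, intervention, life_table, 60)
        b = HealthState.BASELINE_ASCVD
        assert m1[b, HealthState.ACUTE_MI] < m0[b, HealthState.ACUTE_MI]
        assert m1[b, HealthState.ACUTE_IS] < m0[b, HealthState.ACUTE_IS]
        assert m1[b, HealthState.DEAD_CV] < m0[b, HealthState.DEAD_CV]

    def test_recurrence_multipliers(self, params, zero_mortality_table):
        comparator, _ = make_arms(params)
        m = transition_matrix(params, comparator, zero_mortality_table, 60)
        hr = params.effects.hr_recurrent_mi.point
        assert m[HealthState.POST_MI, HealthState.ACUTE_MI] == pytest.approx(
            rate_to_prob(0.0353 * hr), abs=1e-12)
        hr_is = params.effects.hr_recurrent_is.point
        assert m[HealthState.POST_IS, HealthState.ACUTE_IS] == pytest.approx(
            rate_to_prob(0.0172 * hr_is), abs=1e-12)

    def test_post_event_death_multiplier(self, params, zero_mortality_table):
        comparator, _ = make_arms(params)
        m = transition_matrix(params, comparator, zero_mortality_table, 60)
        hr = params.effects.hr_post_event_death.point
        assert m[HealthState.ACUTE_MI, HealthState.DEAD_CV] == pytest.approx(
            rate_to_prob(0.0070 * hr), abs=1e-12)

    def test_acute_survivors_reach_post_state(self, params, zero_mortality_table):
        comparator, _ = make_arms(params)
        m = transition_matrix(params, comparator, zero_mortality_table, 60)
        a = HealthState.ACUTE_MI
        assert m[a, HealthState.POST_MI] == pytest.approx(
            1 - m[a, HealthState.DEAD_CV] - m[a, HealthState.DEAD_NONCV], abs=1e-12)
        assert m[a, a] == 0

    def test_dead_states_absorbing(self, params, life_table):
        comparator, _ = make_arms(params)
        m = transition_matrix(params, comparator, life_table, 70)
        for s in DEAD:
            assert m[s, s] == 1.0
            assert m[s].sum() == 1.0


class TestRunCohort:
    def test_constant_utility_closed_form(self, params, zero_mortality_table):
        p = zero_event_params(params, utility=0.7, horizon=12, discount=0.0)
        comparator, _ = make_arms(p)
        trace = run_cohort(p, comparator, zero_mortality_table)
        assert trace.total_qalys == pytest.approx(0.7 * 12, abs=1e-12)

    def test_two_state_geometric_decay(self, params):
        # alive -> dead with constant probability p: occupancy is (1-p)^k
        rate = 0.05
        ages = np.arange(40, 101, dtype=float)
        table = LifeTable(ages, np.full_like(ages, rate), np.zeros_like(ages))
        p = zero_event_params(params, horizon=20)
        comparator, _ = make_arms(p)
        trace = run_cohort(p, comparator, table)
        prob = 1 - math.exp(-rate)
        for k in range(21):
            assert trace.occupancy[k, HealthState.BASELINE_ASCVD] == pytest.approx(
                (1 - prob) ** k, abs=1e-12)

    def test_occupancy_conservation(self, params, life_table):
        for arm in make_arms(params):
            trace = run_cohort(params, arm, life_table)
            np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
            assert trace.occupancy.min() >= -1e-12

    def test_dead_fraction_monotone(self, params, life_table):
        for arm in make_arms(params):
            trace = run_cohort(params, arm, life_table)
            dead = trace.occupancy[:, DEAD].sum(axis=1)
            assert np.all(np.diff(dead) >= -1e-12)

    def test_intervention_dominance_direction(self, params, life_table):
        comparator, intervention = make_arms(params)
        for horizon in (5, 15, 30):
            p = dataclasses.replace(params, settings=dataclasses.replace(
                params.settings, horizon_years=horizon))
            ta = run_cohort(p, comparator, life_table)
            tb = run_cohort(p, intervention, life_table)
            assert tb.total_qalys >= ta.total_qalys
            assert tb.total_cost >= ta.total_cost

    def test_qalys_decrease_with_discount_rate(self, params, life_table):
        comparator, _ = make_arms(params)
        totals = []
        for rate in (0.0, 0.02, 0.045, 0.08):
            p = _with_value(params, "settings.discount_rate", rate)
            totals.append(run_cohort(p, comparator, life_table).total_qalys)
        assert all(a > b for a, b in zip(totals, totals[1:]))

    def test_horizon_exceeding_table_coverage(self, params):
        ages = np.arange(60, 70, dtype=float)
        short = LifeTable(ages, np.full_like(ages, 0.01), np.zeros_like(ages))
        comparator, _ = make_arms(params)
        with pytest.raises(ValidationError, match="coverage"):
            run_cohort(params, comparator, short)

    def test_trace_export_columns(self, params, life_table):
        comparator, _ = make_arms(params)
        df = run_cohort(params, comparator, life_table).to_frame()
        assert len(df) == params.settings.horizon_years
        for col in ("cycle", "age", "cost_discounted", "qaly_discounted", "arm"):
            assert col in df.columns

    @settings(max_examples=25, deadline=None)
    @given(delta=st.floats(0.0, 3.0), scale=st.floats(0.1, 2.0),
           discount=st.floats(0.0, 0.1))
    def test_conservation_under_parameter_variation(self, params, delta, scale,
                                                    discount):
        life_table = pytest.importorskip("lipidcea.synthetic").default_life_table()
        p = _with_value(params, "baseline.composite",
                        params.baseline.composite.point * scale)
        p = _with_value(p, "effects.ldl_reduction_abs", delta)
        p = _with_value(p, "settings.discount_rate", discount)
        p = dataclasses.replace(p, settings=dataclasses.replace(
            p.settings, horizon_years=10))
        for arm in make_arms(p):
            trace = run_cohort(p, arm, life_table)
            np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)


class TestMicrosimulationOracle:
    """Independent oracle: individual-level simulation with the same
    transition matrices must reproduce cohort totals within Monte-Carlo
    error (3 SE) at 1e5 walkers."""

    N_WALKERS = 100_000

    @pytest.mark.parametrize("arm_index", [0, 1])
    def test_cohort_matches_microsim(self, params, life_table, arm_index):
        from oracles import microsimulate

        arm = make_arms(params)[arm_index]
        trace = run_cohort(params, arm, life_table)
        rng = np.random.default_rng(1234 + arm_index)
        costs, qalys = microsimulate(params, arm, life_table, self.N_WALKERS, rng)
        for sample, cohort_total in ((qalys, trace.total_qalys),
                                     (costs, trace.total_cost)):
            se = sample.std(ddof=1) / math.sqrt(self.N_WALKERS)
            assert abs(sample.mean() - cohort_total) < 3 * se
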