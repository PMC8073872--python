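"""Cohort engine: conservation, tunnels, QALY accrual, microsim agreement."""

import math

import numpy as np
import pytest

from aphasia_cea import (ArmProbs, ModelSpec, UtilityEstimate, UtilityInputs,
                         accrue_qalys, arm_outcomes, cohort_qalys_vector,
                         discount_factor, flat_ageing_index,
                         generate_life_table, linear_ageing_index,
                         microsimulate, run_cohort)

A, G6, G9, G12, D = range(5)


def _probs(p6=0.4, p9=0.1, p12=0.08, r69=0.25, r912=0.2, post=0.2):
    return ArmProbs(p_response6=p6, p_new_response9=p9, p_new_response12=p12,
                    p_relapse_6_9=r69, p_relapse_9_12=r912,
                    p_relapse_post12=post)


def _utilities(ua=0.6, d6=-0.04, d9=-0.02, d12=0.02, index=None):
    deltas = {t: UtilityEstimate(delta=d, se=0.0, n_responders=10,
                                 n_nonresponders=10)
              for t, d in ((6, d6), (9, d9), (12, d12))}
    return UtilityInputs(u_aphasia=ua, deltas=deltas,
                         ageing_index=index or flat_ageing_index())


@pytest.fixture(scope="module")
def base_run(life_table, model_spec):
    return run_cohort(model_spec, _probs(), life_table)


class TestTrace:
    def test_rows_sum_to_one(self, base_run):
        sums = base_run.occupancy.sum(axis=1)
        assert np.abs(sums - 1).max() < 1e-10

    def test_starts_fully_in_aphasia(self, base_run):
        assert base_run.occupancy[0, A] == 1.0
        assert base_run.occupancy[0, 1:].sum() == 0.0

    def test_dead_occupancy_non_decreasing(self, base_run):
        assert (np.diff(base_run.occupancy[:, D]) >= -1e-15).all()

    def test_cohort_fully_absorbed_by_terminal_age(self, base_run,
                                                   model_spec):
        assert 1 - base_run.occupancy[-1, D] < model_spec.living_tolerance

    def test_tunnel_states_hold_occupancy_exactly_one_cycle(self, base_run):
        occ = base_run.occupancy
        # good-response-6m occupied only at the month-6 row (cycle 2);
        # good-response-9m only at month 9 (cycle 3)
        assert occ[2, G6] > 0
        assert np.delete(occ[:, G6], 2).max() == 0.0
        assert occ[3, G9] > 0
        assert np.delete(occ[:, G9], 3).max() == 0.0

    def test_no_new_responses_after_month_12(self, life_table, model_spec):
        # with full relapse between 9 and 12 months and no 12-month
        # responders, the response states stay empty forever after
        probs = _probs(p12=0.0, r912=1.0)
        occ = run_cohort(model_spec, probs, life_table).occupancy
        assert occ[4:, [G6, G9, G12]].max() == 0.0

    def test_zero_mortality_zero_response_stays_in_aphasia(self):
        # keep the modelled ages clear of the life table's forced
        # terminal absorption so mortality really is zero throughout
        lt = generate_life_table(60, 95, base_rate=0.0, growth=0.0)
        spec = ModelSpec(start_age=65, terminal_age=90)
        occ = run_cohort(spec, _probs(0, 0, 0, 0, 0, 0), lt).occupancy
        assert np.allclose(occ[:, A], 1.0)

    def test_three_cycle_hand_multiplied_matrix_chain(self):
        # independent oracle: explicit transition matrices multiplied by
        # hand for the first three cycles (no deaths, simple numbers)
        lt = generate_life_table(60, 90, base_rate=0.0, growth=0.0)
        spec = ModelSpec(start_age=65, terminal_age=90)
        probs = _probs(p6=0.5, p9=0.2, r69=0.1)
        trace = run_cohort(spec, probs, lt)
        s0 = np.array([1, 0, 0, 0, 0.0])
        m_warmup = np.eye(5)                       # cycle 0 -> 1: nothing
        m_assess6 = np.eye(5)
        m_assess6[A, A], m_assess6[A, G6] = 0.5, 0.5
        m_assess9 = np.eye(5)
        m_assess9[A, A], m_assess9[A, G9] = 0.8, 0.2
        m_assess9[G6, G6] = 0.0
        m_assess9[G6, A], m_assess9[G6, G9] = 0.1, 0.9
        expect1 = s0 @ m_warmup
        expect2 = expect1 @ m_assess6
        expect3 = expect2 @ m_assess9
        assert np.allclose(trace.occupancy[1], expect1)
        assert np.allclose(trace.occupancy[2], expect2)
        assert np.allclose(trace.occupancy[3], expect3)

    def test_post12_geometric_decay(self):
        # after month 12 good-response occupancy decays by
        # (1 - relapse) * (1 - death) per cycle
        lt = generate_life_table(60, 120, base_rate=0.02, growth=0.0)
        spec = ModelSpec(start_age=65, terminal_age=110,
                         mortality_multiplier=1.0)
        probs = _probs(post=0.1)
        occ = run_cohort(spec, probs, lt).occupancy
        d = 1 - (1 - 0.02) ** 0.25
        for t in range(4, 20):
            assert occ[t + 1, G12] == pytest.approx(
                occ[t, G12] * 0.9 * (1 - d), rel=1e-12)

    def test_certain_relapse_empties_good_response_at_month_15(self,
                                                               life_table):
        spec = ModelSpec()
        probs = _probs(post=1.0)
        occ = run_cohort(spec, probs, life_table).occupancy
        assert occ[4, G12] > 0          # month 12
        assert occ[5:, G12].max() == 0  # month 15 onwards

    def test_frame_export(self, base_run, tmp_path):
        df = base_run.to_frame()
        assert list(df.columns[:2]) == ["cycle", "age"]
        base_run.to_csv(tmp_path / "trace.csv")
        assert (tmp_path / "trace.csv").exists()


class TestQALYs:
    def test_single_cycle_at_08_accrues_02(self):
        # three months in a state with utility 0.8 is 0.2 QALYs
        lt = generate_life_table(60, 90, base_rate=0.0, growth=0.0)
        spec = ModelSpec(start_age=65, terminal_age=90,
                         discount_rate_qalys=0.0)
        trace = run_cohort(spec, _probs(0, 0, 0, 0, 0, 0), lt)
        accrue_qalys(trace, _utilities(ua=0.8))
        assert trace.qaly_increments[0] == pytest.approx(0.2)

    def test_all_dead_accrues_zero(self, life_table):
        lt = generate_life_table(60, 90, base_rate=1.0, growth=0.0)
        spec = ModelSpec(start_age=65, terminal_age=90)
        trace = run_cohort(spec, _probs(), lt)
        total = accrue_qalys(trace, _utilities())
        # the cohort lives its first cycle, then everyone is dead
        assert trace.qaly_increments[1:].sum() == 0.0
        assert total == trace.qaly_increments[0]

    def test_discounted_year_at_full_health_bounds(self):
        lt = generate_life_table(60, 67, base_rate=0.0, growth=0.0)
        spec = ModelSpec(start_age=65, terminal_age=66.9)
        trace = run_cohort(spec, _probs(0, 0, 0, 0, 0, 0), lt)
        # restrict to the first year (4 cycles)
        trace.occupancy = trace.occupancy[:5]
        total = accrue_qalys(trace, _utilities(ua=1.0, d6=0, d9=0, d12=0))
        assert discount_factor(1, 0.035) < total < 1.0
        assert total > 0.96

    def test_qalys_monotone_in_state_utility_and_discount_rate(
            self, life_table):
        spec_lo = ModelSpec(discount_rate_qalys=0.035)
        spec_hi = ModelSpec(discount_rate_qalys=0.06)
        trace = run_cohort(spec_lo, _probs(), life_table)
        q_base = accrue_qalys(trace, _utilities(ua=0.6), spec_lo)
        q_higher_u = accrue_qalys(trace, _utilities(ua=0.65), spec_lo)
        q_higher_r = accrue_qalys(trace, _utilities(ua=0.6), spec_hi)
        assert q_higher_u > q_base
        assert q_higher_r < q_base

    def test_qalys_bounded_by_life_years_times_max_utility(
            self, base_run):
        u = _utilities()
        total = accrue_qalys(base_run, u)
        u_max = u.u_aphasia + max(d.delta for d in u.deltas.values())
        assert total <= base_run.life_years * max(u_max, u.u_aphasia) + 1e-9

    def test_ageing_decrement_reduces_qalys(self, base_run):
        flat = accrue_qalys(base_run, _utilities())
        aged = accrue_qalys(base_run, _utilities(
            index=linear_ageing_index(annual_decrement=0.003)))
        assert aged < flat

    def test_utility_above_one_rejected(self, base_run):
        with pytest.raises(ValueError):
            accrue_qalys(base_run, _utilities(ua=0.99, d12=0.05))


class TestOutcomesAndInvariance:
    def test_discount_factor_values(self):
        assert discount_factor(0, 0.035) == 1.0
        assert discount_factor(1, 0.035) == pytest.approx(0.96618, abs=5e-6)
        assert discount_factor(7.5, 0.0) == 1.0
        with pytest.raises(ValueError):
            discount_factor(-1, 0.035)

    def test_life_years_invariant_across_arms(self, life_table, model_spec):
        # mortality is identical in every state and arm, so modelled
        # life expectancy cannot differ between arms
        t1 = run_cohort(model_spec, _probs(0.5, 0.2, 0.1, 0.1, 0.1, 0.1),
                        life_table)
        t2 = run_cohort(model_spec, _probs(0.1, 0.0, 0.0, 0.5, 0.5, 0.3),
                        life_table)
        assert t1.life_years == pytest.approx(t2.life_years, rel=1e-12)

    def test_identical_inputs_give_identical_qalys(self, life_table,
                                                   model_spec):
        q1 = accrue_qalys(run_cohort(model_spec, _probs(), life_table),
                          _utilities())
        q2 = accrue_qalys(run_cohort(model_spec, _probs(), life_table),
                          _utilities())
        assert q1 == q2

    def test_arm_outcomes_cost_passthrough(self, base_run):
        cost, qalys = arm_outcomes(base_run, _utilities(), 732.73)
        assert cost == 732.73
        assert qalys == pytest.approx(accrue_qalys(base_run, _utilities()))

    def test_vector_engine_matches_scalar_runs(self, life_table,
                                               model_spec):
        u = _utilities()
        p6 = np.array([0.3, 0.5])
        probs = ArmProbs(p_response6=p6,
                         p_new_response9=np.array([0.1, 0.2]),
                         p_new_response12=np.array([0.05, 0.1]),
                         p_relapse_6_9=np.array([0.2, 0.3]),
                         p_relapse_9_12=np.array([0.2, 0.25]),
                         p_relapse_post12=np.array([0.2, 0.25]))
        vec = cohort_qalys_vector(model_spec, probs, life_table, u,
                                  (np.full(2, -0.04), np.full(2, -0.02),
                                   np.full(2, 0.02)))
        for i in range(2):
            scal = ArmProbs(*[np.asarray(getattr(probs, f))[i] for f in
                              ("p_response6", "p_new_response9",
                               "p_new_response12", "p_relapse_6_9",
                               "p_relapse_9_12", "p_relapse_post12")])
            trace = run_cohort(model_spec, scal, life_table)
            # the engines may truncate the horizon a cycle apart at the
            # living-occupancy tolerance, so compare just above it
            assert vec[i] == pytest.approx(accrue_qalys(trace, u),
                                           rel=1e-7)


class TestMicrosimulationOracle:
    def test_cohort_agrees_with_individual_simulation(self, life_table,
                                                      model_spec):
        # 100,000 simulated individuals vs the cohort matrix arithmetic:
        # QALYs and life-years must agree within 3 Monte-Carlo SEs
        probs = _probs()
        u = _utilities()
        trace = run_cohort(model_spec, probs, life_table)
        cohort_q = accrue_qalys(trace, u)
        sim = microsimulate(model_spec, probs, life_table, u, n=100_000,
                            seed=31)
        assert abs(sim["mean_qalys"] - cohort_q) < 3 * sim["se_qalys"]
        assert abs(sim["mean_life_years"] - trace.life_years) \
            < 3 * sim["se_life_years"]
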