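"""Probabilistic sensitivity analysis and cost-effectiveness outputs."""

import numpy as np
import pandas as pd
import pytest

from aphasia_cea import (ArmCost, ArmTransitions, ModelSpec,
                         ParameterDistributions, PSASample, TransitionSet,
                         UtilityEstimate, UtilityInputs, ceac,
                         flat_ageing_index, incremental_analysis,
                         incremental_pairs, nmb, run_psa, sample_parameters)


def _transitions():
    ts = TransitionSet()
    ts.arms["ct_uc"] = ArmTransitions(arm="ct_uc", r6=40, n6=100, new9=9,
                                      d9=60, new12=5, d12=55, rel69=10,
                                      d69=40, rel912=8, d912=45)
    ts.arms["uc"] = ArmTransitions(arm="uc", r6=20, n6=100, new9=8, d9=80,
                                   new12=6, d12=74, rel69=6, d69=20,
                                   rel912=7, d912=34)
    return ts


def _utilities(se=0.01):
    deltas = {t: UtilityEstimate(delta=d, se=se, n_responders=40,
                                 n_nonresponders=60)
              for t, d in ((6, -0.04), (9, -0.02), (12, 0.05))}
    return UtilityInputs(u_aphasia=0.6, deltas=deltas,
                         ageing_index=flat_ageing_index())


def _dists(zero_variance=False, se=0.01, cost_se=30.0):
    return ParameterDistributions(
        transitions=_transitions(), utilities=_utilities(se),
        arm_costs={"ct_uc": ArmCost("ct_uc", 732.73, cost_se, 100),
                   "uc": ArmCost("uc", 0.0, 0.0, 100)},
        zero_variance=zero_variance)


class TestSampling:
    def test_zero_variance_draw_equals_means(self):
        rng = np.random.default_rng(0)
        draw = sample_parameters(_dists(zero_variance=True), rng, size=3)
        ts = _transitions()
        assert np.allclose(draw.arm_probs["ct_uc"].p_response6,
                           ts.arms["ct_uc"].p_response6)
        assert np.allclose(draw.deltas[2], 0.05)
        assert np.allclose(draw.arm_costs["ct_uc"], 732.73)

    def test_beta_moments_recovered(self):
        # beta(40, 60) has mean 0.4
        rng = np.random.default_rng(1)
        draw = sample_parameters(_dists(), rng, size=10_000)
        p = np.asarray(draw.arm_probs["ct_uc"].p_response6)
        mean, var = 0.4, 0.4 * 0.6 / 101
        assert abs(p.mean() - mean) < 3 * np.sqrt(var / 10_000)
        assert ((p >= 0) & (p <= 1)).all()

    def test_gamma_moment_matching(self):
        rng = np.random.default_rng(2)
        dists = _dists(cost_se=10.0)
        dists.arm_costs["ct_uc"] = ArmCost("ct_uc", 100.0, 10.0, 100)
        draw = sample_parameters(dists, rng, size=20_000)
        c = draw.arm_costs["ct_uc"]
        assert c.mean() == pytest.approx(100.0, abs=3 * 10 / np.sqrt(20_000))
        assert c.std() == pytest.approx(10.0, rel=0.05)
        assert (c >= 0).all()

    def test_boundary_counts_collapse_to_point_mass(self):
        ts = _transitions()
        ts.arms["uc"] = ArmTransitions(arm="uc", r6=0, n6=100, new9=0,
                                       d9=100, new12=0, d12=100, rel69=0,
                                       d69=1, rel912=0, d912=1)
        dists = _dists()
        dists.transitions = ts
        rng = np.random.default_rng(3)
        draw = sample_parameters(dists, rng, size=5)
        assert np.all(np.asarray(draw.arm_probs["uc"].p_response6) == 0.0)

    def test_shared_relapse_draw_beyond_12_months(self):
        rng = np.random.default_rng(4)
        draw = sample_parameters(_dists(), rng, size=100)
        assert np.array_equal(draw.arm_probs["ct_uc"].p_relapse_9_12,
                              draw.arm_probs["ct_uc"].p_relapse_post12)


class TestRunPSA:
    def test_same_seed_identical_samples(self, life_table, model_spec):
        a = run_psa(model_spec, _dists(), life_table, n_iter=50, seed=5)
        b = run_psa(model_spec, _dists(), life_table, n_iter=50, seed=5)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_zero_variance_single_iteration_equals_deterministic(
            self, life_table, model_spec):
        from aphasia_cea import ArmProbs, accrue_qalys, run_cohort
        sample = run_psa(model_spec, _dists(zero_variance=True), life_table,
                         n_iter=1, seed=6)
        ts = _transitions()
        for arm in ("ct_uc", "uc"):
            probs = ArmProbs.from_transitions(ts.arms[arm])
            trace = run_cohort(model_spec, probs, life_table)
            q_det = accrue_qalys(trace, _utilities())
            row = sample.data[sample.data["arm"] == arm].iloc[0]
            assert row["qalys"] == pytest.approx(q_det, rel=1e-12)

    def test_mean_increment_matches_deterministic_for_symmetric_dists(
            self, life_table, model_spec):
        # costs are normal-ish gamma and deltas normal; the mean
        # incremental cost over draws approaches the deterministic one
        sample = run_psa(model_spec, _dists(), life_table, n_iter=4000,
                         seed=7)
        cost = sample.arm_matrix("cost")
        dc = (cost["ct_uc"] - cost["uc"]).to_numpy()
        se = dc.std(ddof=1) / np.sqrt(len(dc))
        assert abs(dc.mean() - 732.73) < 3 * se


class TestIncrementalAnalysis:
    def _sample_from(self, rows):
        return PSASample(data=pd.DataFrame(rows))

    def test_printed_subgroup_increments_reproduce_their_icer(self):
        # a moderate-severity comparison with increments 776.65 and
        # 0.0568 has ICER 13,673 to the nearest pound
        rows = [{"iteration": 0, "arm": "ct_uc", "cost": 814.44,
                 "qalys": 4.3225},
                {"iteration": 0, "arm": "ac_uc", "cost": 37.79,
                 "qalys": 4.2657},
                {"iteration": 1, "arm": "ct_uc", "cost": 814.44,
                 "qalys": 4.3225},
                {"iteration": 1, "arm": "ac_uc", "cost": 37.79,
                 "qalys": 4.2657}]
        inc = incremental_analysis(self._sample_from(rows), "ct_uc",
                                   "ac_uc")
        assert inc.delta_cost == pytest.approx(776.65)
        assert inc.delta_qalys == pytest.approx(0.0568)
        assert round(inc.icer) == 13673
        assert inc.label == "icer"

    @pytest.mark.parametrize("dc,dq,label", [
        (100.0, -0.01, "dominated"),
        (-100.0, 0.01, "dominant"),
        (0.0, 0.01, "dominant"),
        (-1.0, -0.01, "undefined (southwest quadrant)"),
    ])
    def test_quadrant_labels(self, dc, dq, label):
        rows = []
        for it in range(2):
            rows.append({"iteration": it, "arm": "new", "cost": 500 + dc,
                         "qalys": 4 + dq})
            rows.append({"iteration": it, "arm": "old", "cost": 500.0,
                         "qalys": 4.0})
        inc = incremental_analysis(self._sample_from(rows), "new", "old")
        assert inc.label == label
        assert inc.icer is None

    def test_zero_qaly_difference_is_undefined_not_an_error(self):
        rows = []
        for it in range(2):
            rows.append({"iteration": it, "arm": "new", "cost": 600.0,
                         "qalys": 4.0})
            rows.append({"iteration": it, "arm": "old", "cost": 500.0,
                         "qalys": 4.0})
        inc = incremental_analysis(self._sample_from(rows), "new", "old")
        assert inc.label == "undefined"
        assert inc.icer is None

    def test_credible_interval_is_percentile_based(self, life_table,
                                                   model_spec):
        sample = run_psa(model_spec, _dists(), life_table, n_iter=2000,
                         seed=8)
        inc = incremental_analysis(sample, "ct_uc", "uc")
        pairs = incremental_pairs(sample, "ct_uc", "uc")
        lo, hi = np.percentile(pairs["delta_cost"], [2.5, 97.5])
        assert inc.ci_cost == pytest.approx((lo, hi))
        assert inc.ci_cost[0] <= inc.delta_cost <= inc.ci_cost[1]
        assert inc.ci_qalys[0] <= inc.delta_qalys <= inc.ci_qalys[1]


class TestNMB:
    def test_arithmetic(self):
        assert nmb(732.73, 0.02, 30_000) == pytest.approx(-132.73)
        assert nmb(0.0, 0.5, 0) == 0.0

    def test_strictly_increasing_in_threshold_for_positive_qalys(self):
        vals = [nmb(100.0, 0.3, lam) for lam in (0, 1000, 10_000)]
        assert vals[0] < vals[1] < vals[2]

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            nmb(0, 0, -1)


class TestCEAC:
    def _hand_sample(self):
        # 4 iterations, 2 arms; NMB winners countable by hand
        rows = []
        costs_a = [100, 100, 100, 100]
        qalys_a = [1.0, 1.0, 1.0, 1.0]
        costs_b = [0, 0, 250, 50]
        qalys_b = [0.99, 1.02, 1.0, 1.0]
        for i in range(4):
            rows.append({"iteration": i, "arm": "a", "cost": costs_a[i],
                         "qalys": qalys_a[i]})
            rows.append({"iteration": i, "arm": "b", "cost": costs_b[i],
                         "qalys": qalys_b[i]})
        return PSASample(data=pd.DataFrame(rows))

    def test_hand_counted_fractions(self):
        table = ceac(self._hand_sample(), thresholds=(0, 20_000))
        # lambda=0: NMB = -cost; b wins iterations 0,1,3; a wins 2
        row0 = table[table["threshold"] == 0].iloc[0]
        assert row0["a"] == pytest.approx(0.25)
        assert row0["b"] == pytest.approx(0.75)
        # lambda=20k: iteration 0: a by 100; 1: b by 500; 2: a by 150;
        # 3: b by 50
        row1 = table[table["threshold"] == 20_000].iloc[0]
        assert row1["a"] == pytest.approx(0.5)
        assert row1["b"] == pytest.approx(0.5)

    def test_probabilities_sum_to_one_across_arms(self, life_table,
                                                  model_spec):
        sample = run_psa(model_spec, _dists(), life_table, n_iter=400,
                         seed=9)
        table = ceac(sample, thresholds=tuple(range(0, 50_001, 5000)))
        arms = [c for c in table.columns if c != "threshold"]
        assert np.allclose(table[arms].sum(axis=1), 1.0, atol=1e-12)

    def test_zero_threshold_rewards_cheapest_arm(self, life_table,
                                                 model_spec):
        sample = run_psa(model_spec, _dists(), life_table, n_iter=200,
                         seed=10)
        table = ceac(sample, thresholds=(0,))
        assert table.iloc[0]["uc"] == 1.0      # zero-cost comparator

    def test_everywhere_dominant_arm_has_probability_one(self):
        rows = []
        for i in range(3):
            rows.append({"iteration": i, "arm": "good", "cost": 10.0,
                         "qalys": 2.0})
            rows.append({"iteration": i, "arm": "bad", "cost": 20.0,
                         "qalys": 1.0})
        table = ceac(PSASample(data=pd.DataFrame(rows)),
                     thresholds=(0, 10_000, 100_000))
        assert (table["good"] == 1.0).all()

    def test_exact_ties_split_evenly(self):
        rows = [{"iteration": 0, "arm": "a", "cost": 10.0, "qalys": 1.0},
                {"iteration": 0, "arm": "b", "cost": 10.0, "qalys": 1.0}]
        table = ceac(PSASample(data=pd.DataFrame(rows)), thresholds=(0,))
        assert table.iloc[0]["a"] == pytest.approx(0.5)
        assert table.iloc[0]["b"] == pytest.approx(0.5)

    def test_empty_sample_rejected(self):
        empty = PSASample(data=pd.DataFrame(
            columns=["iteration", "arm", "cost", "qalys"]))
        with pytest.raises(ValueError):
            ceac(empty, thresholds=(0,))


def test_plots_render_without_display(life_table, model_spec, tmp_path):
    import matplotlib
    matplotlib.use("Agg")
    from aphasia_cea import plot_ce_plane, plot_ceac
    sample = run_psa(model_spec, _dists(), life_table, n_iter=50, seed=11)
    ax = plot_ce_plane(incremental_pairs(sample, "ct_uc", "uc"))
    ax.figure.savefig(tmp_path / "plane.png")
    ax2 = plot_ceac(ceac(sample, thresholds=tuple(range(0, 50_001, 10_000))))
    ax2.figure.savefig(tmp_path / "ceac.png")
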