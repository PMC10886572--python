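"""Signature scoring, group contrasts, KM/log-rank and the cutpoint scan."""

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test

from sevmir.clinical import (
    compare_groups,
    km_curve,
    km_logrank,
    logrank_statistic,
    occult_contrast,
    optimal_cutpoint_survival,
    signature_score,
)
from sevmir.io_formats import ClinicalTable
from sevmir.synthetic_data import CohortConfig, SimulationConfig, simulate_clinical_cohort

from oracles import hand_km, hand_logrank


def make_clinical(expr_cols, times=None, events=None, **stage_cols):
    n = len(next(iter(expr_cols.values())))
    data = pd.DataFrame(
        {
            "time": times if times is not None else np.arange(1, n + 1) * 10.0,
            "event": events if events is not None else np.ones(n, dtype=int),
            **stage_cols,
            **expr_cols,
        },
        index=pd.Index([f"p{i}" for i in range(n)], name="patient_id"),
    )
    return ClinicalTable(data=data, expression_columns=list(expr_cols))


class TestSignatureScore:
    def test_single_mirna_scores_are_zscores(self):
        expr = np.array([2.0, 8.0, 32.0, 128.0]) - 1  # log2(x+1) = 1,3,5,7
        table = make_clinical({"mirA": expr})
        scores = signature_score(table, ["mirA"])["score"]
        logs = np.log2(expr + 1)
        expected = (logs - logs.mean()) / logs.std(ddof=0)
        assert np.allclose(scores, expected)

    def test_constant_columns_excluded_then_error(self):
        table = make_clinical({"mirA": np.full(5, 7.0)})
        with pytest.raises(ValueError, match="zero variance"):
            signature_score(table, ["mirA"])

    def test_affine_rescaling_of_one_mirna_is_absorbed(self, rng):
        base = rng.lognormal(8, 1, size=50)
        other = rng.lognormal(6, 1, size=50)
        t1 = make_clinical({"mirA": base, "mirB": other})
        # x -> 2^(a*log2(x+1)+b) - 1 is affine on the log2(x+1) scale
        rescaled = np.power(2.0, 3.0 * np.log2(base + 1) + 2.0) - 1
        t2 = make_clinical({"mirA": rescaled, "mirB": other})
        s1 = signature_score(t1, ["mirA", "mirB"])["score"]
        s2 = signature_score(t2, ["mirA", "mirB"])["score"]
        assert np.allclose(s1, s2)

    def test_recovers_latent_score_in_simulated_cohort(self):
        cfg = SimulationConfig(seed=71)
        cfg.cohort = CohortConfig(n_patients=300)
        sig = [f"mir-{i}" for i in range(8)]
        table, truth = simulate_clinical_cohort(cfg, sig)
        scores = signature_score(table, sig)["score"]
        z = np.array([truth.patient_scores[p] for p in table.patient_ids])
        assert np.corrcoef(scores, z)[0, 1] > 0.7

    def test_missing_signature_errors(self):
        table = make_clinical({"mirA": np.arange(5.0) + 1})
        with pytest.raises(ValueError, match="no signature"):
            signature_score(table, ["mirZ"])


class TestCompareGroups:
    def test_identical_groups_null(self):
        scores = pd.Series(np.tile([1.0, 2.0, 3.0, 4.0], 2))
        groups = pd.Series(["a"] * 4 + ["b"] * 4)
        res = compare_groups(scores, groups)
        assert abs(res.statistic) < 1e-9
        assert res.p == pytest.approx(1.0)

    def test_welch_matches_scipy(self, rng):
        from scipy import stats

        a, b = rng.normal(0, 1, 30), rng.normal(1, 2, 40)
        scores = pd.Series(np.concatenate([a, b]))
        groups = pd.Series(["a"] * 30 + ["b"] * 40)
        res = compare_groups(scores, groups)
        t_ref, p_ref = stats.ttest_ind(a, b, equal_var=False)
        assert res.statistic == pytest.approx(t_ref)
        assert res.p == pytest.approx(p_ref)

    def test_shifted_groups_detected(self, rng):
        hits = 0
        for _ in range(30):
            a, b = rng.normal(0, 1, 100), rng.normal(1, 1, 100)
            res = compare_groups(
                pd.Series(np.concatenate([a, b])),
                pd.Series(["a"] * 100 + ["b"] * 100),
            )
            hits += res.p < 0.01
        assert hits >= 27

    def test_anova_null_calibration(self, rng):
        rejections = 0
        for _ in range(200):
            scores = pd.Series(rng.normal(size=60))
            groups = pd.Series(np.repeat(["a", "b", "c"], 20))
            res = compare_groups(scores, groups, design="multi_group")
            rejections += res.p < 0.05
        assert 2 <= rejections <= 22  # ~5% of 200

    def test_multi_group_returns_tukey_table(self, rng):
        scores = pd.Series(rng.normal(size=90))
        groups = pd.Series(np.repeat(["a", "b", "c"], 30))
        res = compare_groups(scores, groups, design="multi_group")
        assert len(res.pairwise) == 3
        assert set(res.pairwise.columns) >= {"group_a", "group_b", "p_adjusted"}

    def test_small_group_errors_naming_it(self):
        scores = pd.Series([1.0, 2.0, 3.0])
        groups = pd.Series(["a", "a", "b"])
        with pytest.raises(ValueError, match="'b'"):
            compare_groups(scores, groups)

    def test_missing_labels_dropped_and_counted(self, rng):
        scores = pd.Series(rng.normal(size=10))
        groups = pd.Series(["a"] * 4 + ["b"] * 4 + [None, None])
        res = compare_groups(scores, groups)
        assert res.n_dropped == 2


class TestOccult:
    def test_contrasts_on_planted_cohort(self):
        cfg = SimulationConfig(seed=72)
        cfg.cohort = CohortConfig(n_patients=400)
        sig = [f"mir-{i}" for i in range(8)]
        table, _ = simulate_clinical_cohort(cfg, sig)
        scores = signature_score(table, sig)["score"]
        res = occult_contrast(scores, table)
        assert res["pN0_vs_pN_positive"]["status"] == "ok"
        assert res["pN0_vs_pN_positive"]["mean_diff_positive_minus_negative"] > 0
        assert res["occult_within_cN0"]["status"] == "ok"

    def test_no_occult_cases_skipped(self):
        cfg = SimulationConfig(seed=73)
        cfg.cohort = CohortConfig(n_patients=120, cn_false_negative_rate=0.0)
        sig = ["mir-1"]
        table, _ = simulate_clinical_cohort(cfg, sig)
        scores = signature_score(table, sig)["score"]
        res = occult_contrast(scores, table)
        assert res["occult_within_cN0"]["status"] == "skipped"


class TestKaplanMeier:
    def test_four_deaths_no_censoring_steps(self):
        curve = km_curve([1, 2, 3, 4], [1, 1, 1, 1])
        assert np.allclose(curve["survival"], [0.75, 0.5, 0.25, 0.0])

    def test_km_equals_empirical_survivor_without_censoring(self, rng):
        times = rng.integers(1, 30, size=25).astype(float)
        events = np.ones(25, dtype=int)
        curve = km_curve(times, events)
        for t, s in zip(curve["time"], curve["survival"]):
            assert s == pytest.approx((times > t).mean())

    def test_km_matches_hand_tabulation_with_censoring(self, rng):
        times = rng.integers(1, 15, size=20).astype(float)
        events = rng.integers(0, 2, size=20)
        events[0] = 1
        curve = km_curve(times, events)
        assert list(zip(curve["time"], curve["survival"])) == pytest.approx(
            hand_km(times, events)
        )


class TestLogrank:
    def test_identical_groups_zero_statistic(self):
        times = [1, 1, 2, 2, 3, 3]
        events = [1, 1, 1, 1, 1, 1]
        group = [True, False, True, False, True, False]
        stat, p = logrank_statistic(times, events, group)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_six_patient_hand_tabulation(self):
        times = [1, 2, 3, 4, 5, 6]
        events = [1, 1, 1, 1, 1, 1]
        group = [False, False, False, True, True, True]
        stat, _ = logrank_statistic(times, events, group)
        assert stat == pytest.approx(hand_logrank(times, events, group))

    def test_matches_lifelines_on_random_instances(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 60))
            times = rng.exponential(50, n).round() + 1
            events = rng.integers(0, 2, n)
            group = rng.integers(0, 2, n).astype(bool)
            if events.sum() == 0 or group.all() or not group.any():
                continue
            stat, p = logrank_statistic(times, events, group)
            ref = logrank_test(times[group], times[~group], events[group], events[~group])
            assert stat == pytest.approx(ref.test_statistic)
            assert p == pytest.approx(ref.p_value)

    def test_invariant_to_monotone_time_relabeling(self, rng):
        n = 30
        times = rng.exponential(50, n).round() + 1
        events = rng.integers(0, 2, n)
        events[:3] = 1
        group = np.arange(n) % 2 == 0
        s1, _ = logrank_statistic(times, events, group)
        s2, _ = logrank_statistic(np.log(times + 1), events, group)
        assert s1 == pytest.approx(s2)

    def test_no_events_errors(self):
        with pytest.raises(ValueError, match="event"):
            logrank_statistic([1, 2], [0, 0], [True, False])


@pytest.fixture(scope="module")
def cohort():
    cfg = SimulationConfig(seed=74)
    cfg.cohort = CohortConfig(n_patients=250, hazard_coefficient=1.0)
    sig = [f"mir-{i}" for i in range(8)]
    table, _ = simulate_clinical_cohort(cfg, sig)
    scores = signature_score(table, sig)["score"]
    return scores, table.data["time"].to_numpy(), table.data["event"].to_numpy()


class TestCutpoint:
    def test_planted_hazard_detected_high_arm_worse(self, cohort):
        scores, times, events = cohort
        res = optimal_cutpoint_survival(scores, times, events)
        assert res.p < 0.05
        assert res.high_arm_worse
        assert res.selection_biased

    def test_minimal_p_not_above_median_split(self, cohort):
        scores, times, events = cohort
        res = optimal_cutpoint_survival(scores, times, events)
        median_cut = scores.median()
        _, p_median = logrank_statistic(times, events, scores.to_numpy() > median_cut)
        assert res.p <= p_median + 1e-12

    def test_arm_size_floor_respected(self, cohort):
        scores, times, events = cohort
        res = optimal_cutpoint_survival(scores, times, events)
        floor = max(10, int(np.ceil(0.1 * len(scores))))
        assert min(res.scan["n_low"].min(), res.scan["n_high"].min()) >= floor

    def test_all_equal_scores_errors(self):
        scores = pd.Series(np.zeros(40))
        with pytest.raises(ValueError, match="admissible"):
            optimal_cutpoint_survival(
                scores, np.arange(1.0, 41.0), np.ones(40, dtype=int)
            )

    def test_permutation_p_reported_and_in_range(self, cohort):
        scores, times, events = cohort
        res = optimal_cutpoint_survival(
            scores, times, events, grid_policy="quantile:15",
            n_permutations=99, seed=5,
        )
        assert 0 < res.p_permutation <= 1
        assert res.p_permutation >= res.p  # adjustment can only be less extreme
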