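"""ROC/AUC machinery, thresholds, stratification, group tests, correlation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from pttkit import (
    auc_p_value,
    bootstrap_ci,
    cohort_to_dataframe,
    correlate,
    evaluate_auc,
    group_compare,
    ks_normality,
    quartile_table,
    roc_auc,
    roc_curve_points,
    simulate_cohort,
    stratification_fixture_cohort,
    stratify_by_ptt,
    threshold_at_sensitivity,
    threshold_at_specificity,
    threshold_metrics,
)
from pttkit.synthetic import CohortParams


def pairwise_auc_oracle(scores, labels):
    """Exhaustive positive/negative pair counting with half-credit ties."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (pos.size * neg.size)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3, 4, 5], [0, 0, 0, 1, 1]) == 1.0

    def test_five_sixths_example(self):
        scores = [1, 2, 3, 2.5, 4]
        labels = [0, 0, 0, 1, 1]
        assert roc_auc(scores, labels) == pytest.approx(5 / 6)

    def test_label_inversion_symmetry(self, rng):
        scores = rng.normal(size=30)
        labels = rng.random(30) < 0.4
        labels[0], labels[1] = True, False
        assert roc_auc(scores, labels) == pytest.approx(1 - roc_auc(scores, ~labels))

    def test_matches_pairwise_oracle_and_sklearn(self, rng):
        for _ in range(40):
            n = int(rng.integers(6, 40))
            scores = rng.integers(0, 8, size=n).astype(float)  # forces ties
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            auc = roc_auc(scores, labels)
            assert auc == pytest.approx(pairwise_auc_oracle(scores, labels), abs=1e-12)
            assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_equals_trapezoidal_area_under_empirical_roc(self, rng):
        scores = rng.integers(0, 10, size=60).astype(float)
        labels = rng.random(60) < 0.5
        labels[:2] = [True, False]
        pts = roc_curve_points(scores, labels)
        area = np.trapezoid(pts["tpr"], pts["fpr"])
        assert roc_auc(scores, labels) == pytest.approx(area, abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=50)
        labels = rng.random(50) < 0.5
        labels[:2] = [True, False]
        assert roc_auc(np.exp(scores), labels) == pytest.approx(
            roc_auc(scores, labels), abs=1e-12
        )

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [True, True])


class TestBootstrap:
    def test_perfect_separation_gives_degenerate_interval(self):
        scores = np.concatenate([np.zeros(20), np.ones(20)])
        labels = np.concatenate([np.zeros(20, bool), np.ones(20, bool)])
        lo, hi = bootstrap_ci(scores, labels, n_boot=300, seed=1)
        assert lo == hi == 1.0

    def test_same_seed_reproducible(self, rng):
        scores = rng.normal(size=60)
        labels = rng.random(60) < 0.5
        labels[:2] = [True, False]
        a = bootstrap_ci(scores, labels, n_boot=400, seed=5)
        b = bootstrap_ci(scores, labels, n_boot=400, seed=5)
        assert a == b

    def test_interval_brackets_point_estimate(self, rng):
        scores = rng.normal(size=80) + np.linspace(0, 1, 80)
        labels = np.arange(80) % 2 == 0
        res = evaluate_auc(scores, labels, n_boot=400, seed=2)
        assert res.ci_low <= res.auc <= res.ci_high


class TestAucPValue:
    def test_full_separation_is_decisive(self):
        scores = np.concatenate([np.arange(30), 100 + np.arange(30)]).astype(float)
        labels = np.repeat([False, True], 30)
        assert auc_p_value(scores, labels) < 1e-6

    def test_all_tied_carries_no_evidence(self):
        assert auc_p_value([1.0, 1.0, 1.0, 1.0], [True, True, False, False]) == 1.0


class TestThresholdMetrics:
    def test_clean_split(self):
        m = threshold_metrics([7.0, 9.0], [False, True], 8.0)
        assert (m.sensitivity, m.specificity, m.npv) == (1.0, 1.0, 1.0)
        assert (m.tp, m.fp, m.tn, m.fn) == (1, 0, 1, 0)

    def test_all_negative_predictions_flag_ppv(self):
        scores = [1.0, 2.0, 3.0, 4.0]
        labels = [False, True, False, True]
        m = threshold_metrics(scores, labels, 100.0)
        assert math.isnan(m.ppv) and "ppv" in m.undefined
        assert m.npv == pytest.approx(0.5)  # complement of prevalence

    def test_counts_match_quadruple_loop_oracle(self, rng):
        scores = rng.integers(0, 12, size=50).astype(float)
        labels = rng.random(50) < 0.5
        thr = 6.0
        m = threshold_metrics(scores, labels, thr)
        tp = fp = tn = fn = 0
        for s, l in zip(scores, labels):
            if s >= thr and l:
                tp += 1
            elif s >= thr and not l:
                fp += 1
            elif s < thr and not l:
                tn += 1
            else:
                fn += 1
        assert (m.tp, m.fp, m.tn, m.fn) == (tp, fp, tn, fn)
        assert m.n_pos == tp + fn and m.n_neg == tn + fp


class TestThresholdSelection:
    def test_perfectly_separated(self):
        scores = [1.0, 2.0, 8.0, 9.0]
        labels = [False, False, True, True]
        _, m = threshold_at_specificity(scores, labels, 0.70)
        assert m.specificity == 1.0 and m.sensitivity == 1.0

    def test_zero_target_takes_most_sensitive_threshold(self):
        scores = [1.0, 2.0, 3.0, 4.0]
        labels = [False, True, False, True]
        _, m = threshold_at_specificity(scores, labels, 0.0)
        assert m.sensitivity == 1.0

    def test_agrees_with_exhaustive_scan(self, rng):
        scores = rng.normal(size=60)
        labels = rng.random(60) < 0.45
        labels[:2] = [True, False]
        thr, m = threshold_at_specificity(scores, labels, 0.70)
        # oracle: scan all candidate thresholds, keep min spec >= target,
        # break ties toward sensitivity
        uniq = np.unique(scores)
        cands = np.concatenate([[-np.inf], (uniq[:-1] + uniq[1:]) / 2, [np.inf]])
        best = None
        for c in cands:
            mm = threshold_metrics(scores, labels, c)
            if mm.specificity >= 0.70:
                key = (mm.specificity, -mm.sensitivity)
                if best is None or key < best[0]:
                    best = (key, mm)
        assert m.specificity == best[1].specificity
        assert m.sensitivity == best[1].sensitivity

    def test_sensitivity_variant(self, rng):
        scores = rng.normal(size=50)
        labels = rng.random(50) < 0.5
        labels[:2] = [True, False]
        _, m = threshold_at_sensitivity(scores, labels, 0.70)
        assert m.sensitivity >= 0.70


class TestStratification:
    def test_reference_bin_percentages(self):
        table = stratify_by_ptt(stratification_fixture_cohort(), edges=(8, 12))
        assert table.n == (46, 29, 8)
        assert table.n_positive == (13, 16, 7)
        assert table.pct_positive == (28, 55, 88)
        assert table.pooled_percent_above_first_edge() == 62
        assert table.n_total == 83

    def test_single_bin_no_positives(self):
        df = pd.DataFrame(
            {"patient_id": ["a", "b"], "ptt_s": [5.0, 6.0], "nptt": [5.0, 6.0],
             "rr_s": [1.0, 1.0], "dd_grade": [0, 0], "mvr_grade": [0, 0],
             "dd_relevant": [False, False], "mvr_relevant": [False, False]}
        )
        table = stratify_by_ptt(df, edges=(8, 12))
        assert table.n == (2, 0, 0)
        assert table.pct_positive == (0, 0, 0)

    def test_matches_filter_and_count_oracle(self):
        df = cohort_to_dataframe(simulate_cohort(CohortParams(n_total=150, seed=6)))
        table = stratify_by_ptt(df, edges=(8, 12), outcome="dd_relevant")
        pos = df.dd_relevant.to_numpy(bool)
        v = df.ptt_s.to_numpy()
        for k, (lo, hi) in enumerate([(-np.inf, 8), (8, 12), (12, np.inf)]):
            sel = (v >= lo) & (v < hi)
            assert table.n[k] == int(sel.sum())
            assert table.n_positive[k] == int(pos[sel].sum())
        assert sum(table.n) == len(df)

    def test_half_up_rounding(self):
        from pttkit.diagnostics import round_half_up_percent

        assert round_half_up_percent(7, 8) == 88
        assert round_half_up_percent(1, 8) == 13  # 12.5 rounds up


class TestQuartiles:
    def _frame(self, values):
        n = len(values)
        return pd.DataFrame(
            {"patient_id": [f"p{i}" for i in range(n)], "ptt_s": values,
             "nptt": values, "rr_s": np.ones(n), "dd_grade": np.zeros(n, int),
             "mvr_grade": np.zeros(n, int), "dd_relevant": np.zeros(n, bool),
             "mvr_relevant": np.zeros(n, bool)}
        )

    def test_linear_interpolation_boundaries(self):
        qt = quartile_table(self._frame(np.arange(1.0, 9.0)), variable="nptt")
        assert qt.boundaries == pytest.approx((2.75, 4.5, 6.25))
        assert qt.sizes == (2, 2, 2, 2)

    def test_identical_values_all_in_first_group(self):
        qt = quartile_table(self._frame(np.full(8, 3.0)), variable="nptt")
        assert qt.sizes == (8, 0, 0, 0)

    def test_83_records_split_21_21_20_21(self, rng):
        values = rng.normal(10, 2, size=83)
        qt = quartile_table(self._frame(values), variable="nptt")
        assert qt.sizes == (21, 21, 20, 21)

    def test_summary_contains_median_and_binary_percent(self):
        df = cohort_to_dataframe(simulate_cohort(CohortParams(n_total=80, seed=8)))
        qt = quartile_table(df, variable="nptt")
        stats = set(qt.summary["stat"])
        assert {"median", "q25", "q75", "pct"} <= stats


class TestGroupCompare:
    def test_kruskal_hand_computed_h(self):
        res = group_compare([1, 2, 3, 4], ["a", "a", "b", "b"], test="kruskal")
        assert res.statistic == pytest.approx(2.4)
        assert res.test_name == "kruskal-wallis"

    def test_three_group_default_is_kruskal(self, rng):
        values = rng.normal(size=30)
        labels = np.repeat(["a", "b", "c"], 10)
        assert group_compare(values, labels).test_name == "kruskal-wallis"

    def test_label_permutation_symmetry(self, rng):
        values = rng.normal(size=30)
        labels = np.repeat(["a", "b", "c"], 10)
        a = group_compare(values, labels)
        perm = {"a": "c", "b": "a", "c": "b"}
        b = group_compare(values, np.array([perm[l] for l in labels]))
        assert a.statistic == pytest.approx(b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_ttest_falls_back_for_tiny_group(self, rng):
        values = np.concatenate([rng.normal(size=20), [1.0]])
        labels = np.array(["a"] * 20 + ["b"])
        res = group_compare(values, labels, test="ttest")
        assert res.test_name == "rank-sum"

    def test_ttest_used_when_both_groups_normal(self, rng):
        values = np.concatenate([rng.normal(0, 1, 40), rng.normal(0.5, 1, 40)])
        labels = np.repeat(["a", "b"], 40)
        res = group_compare(values, labels, test="ttest")
        assert res.test_name == "t-test"


class TestCorrelate:
    def test_linear_pearson_is_one(self):
        x = np.arange(10.0)
        assert correlate(x, 2 * x + 1, "pearson") == pytest.approx(1.0)

    def test_cubic_spearman_one_pearson_below(self):
        x = np.linspace(-2, 2, 15)
        y = x**3
        assert correlate(x, y, "spearman") == pytest.approx(1.0)
        assert correlate(x, y, "pearson") < 1.0

    def test_matches_covariance_formula(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        r = correlate(x, y, "pearson")
        oracle = np.cov(x, y, ddof=1)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_is_undefined(self):
        assert math.isnan(correlate(np.ones(5), np.arange(5.0), "pearson"))


class TestNormalityCheck:
    def test_gaussian_sample_passes(self, rng):
        assert ks_normality(rng.normal(size=200)) > 0.05

    def test_heavy_skew_fails(self, rng):
        assert ks_normality(np.exp(rng.normal(size=400) * 1.5)) < 0.05
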