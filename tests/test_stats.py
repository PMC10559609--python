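"""Diagnostic statistics: exact values, independent oracles, invariants."""

import numpy as np
import pytest
from scipy import stats as sps

from laryngoscreen import (
    ConfusionCounts,
    binomial_ci,
    build_report,
    cohens_kappa,
    compare_paired_classifiers,
    confusion_metrics,
    iou,
    mcnemar_test,
    median_iou,
    metric_with_ci,
    roc_auc,
)


class TestConfusionMetrics:
    def test_two_hundred_video_competition_row(self):
        """120 cancer / 80 non-cancer with 114 and 74 correct reproduces the
        0.940/0.950/0.925/0.950/0.925 metric row."""
        c = ConfusionCounts(tp=114, fn=6, fp=6, tn=74)
        m = confusion_metrics(c)
        assert round(m["accuracy"], 3) == 0.940
        assert round(m["sensitivity"], 3) == 0.950
        assert round(m["specificity"], 3) == 0.925
        assert round(m["ppv"], 3) == 0.950
        assert round(m["npv"], 3) == 0.925

    def test_zero_denominator_is_undefined_not_zero(self):
        m = confusion_metrics(ConfusionCounts(tp=0, fn=0, fp=2, tn=8))
        assert m["sensitivity"] is None
        assert m["specificity"] == 0.8

    def test_perfect_classifier(self):
        m = confusion_metrics(ConfusionCounts(tp=5, fn=0, fp=0, tn=5))
        assert all(v == 1.0 for v in m.values())

    def test_counts_must_be_sane(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fn=0, fp=0, tn=1)
        with pytest.raises(ValueError):
            ConfusionCounts(tp=0, fn=0, fp=0, tn=0)


def brute_force_clopper_pearson(k, n, level=0.95, grid=200001):
    """Invert the binomial tail tests by scanning p on a fine grid."""
    alpha = 1 - level
    ps = np.linspace(0, 1, grid)
    upper_tail = sps.binom.sf(k - 1, n, ps)  # P(X >= k | p)
    lower_tail = sps.binom.cdf(k, n, ps)  # P(X <= k | p)
    low = 0.0 if k == 0 else ps[np.searchsorted(upper_tail >= alpha / 2, True)]
    high = 1.0 if k == n else ps[::-1][np.searchsorted((lower_tail >= alpha / 2)[::-1], True)]
    return float(low), float(high)


class TestBinomialCI:
    def test_zero_successes_lower_bound_is_zero(self):
        low, high = binomial_ci(0, 20, method="clopper_pearson")
        assert low == 0.0
        assert 0 < high < 1

    def test_wald_reproduces_printed_video_cis(self):
        low, high = binomial_ci(114, 120, method="wald")
        assert (round(low, 3), round(high, 3)) == (0.911, 0.989)
        low, high = binomial_ci(74, 80, method="wald")
        assert (round(low, 3), round(high, 3)) == (0.867, 0.983)

    def test_clopper_pearson_matches_tail_inversion(self):
        for k, n in [(188, 200), (3, 10), (10, 10), (0, 7), (57, 60)]:
            got = binomial_ci(k, n, method="clopper_pearson")
            expected = brute_force_clopper_pearson(k, n)
            assert got[0] == pytest.approx(expected[0], abs=2e-4)
            assert got[1] == pytest.approx(expected[1], abs=2e-4)

    def test_cp_contains_estimate_and_is_wider_than_wald_low(self):
        cp = binomial_ci(188, 200, method="clopper_pearson")
        wald = binomial_ci(188, 200, method="wald")
        assert cp[0] < 0.94 < cp[1]
        assert cp[0] < wald[0]  # exact interval reaches lower at the bottom

    def test_coverage_property(self):
        """Empirical CP coverage >= nominal minus 3 MC standard errors."""
        n, level, sims = 50, 0.95, 2000
        rng = np.random.default_rng(42)
        for p in (0.1, 0.5, 0.9):
            ks = rng.binomial(n, p, size=sims)
            covered = 0
            for k in np.unique(ks):
                low, high = binomial_ci(int(k), n, level=level)
                if low <= p <= high:
                    covered += int(np.sum(ks == k))
            rate = covered / sims
            mc_err = np.sqrt(level * (1 - level) / sims)
            assert rate >= level - 3 * mc_err

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError):
            binomial_ci(1, 2, level=1.5)

    def test_metric_with_ci_ordering_invariant(self):
        m = metric_with_ci(74, 80, method="clopper_pearson")
        assert 0 <= m.ci_low <= m.estimate <= m.ci_high <= 1


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _ = roc_auc([0.9, 0.8, 0.2, 0.1], [True, True, False, False])
        assert auc == 1.0

    def test_all_ties_give_half(self):
        auc, _ = roc_auc([0.5] * 10, [True] * 5 + [False] * 5)
        assert auc == 0.5

    def test_three_of_four_concordant_pairs(self):
        auc, _ = roc_auc([0.9, 0.4, 0.5, 0.1], [True, True, False, False])
        assert auc == 0.75

    def test_pairwise_equals_trapezoid_and_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(100):
            n = int(rng.integers(4, 40))
            scores = rng.choice(rng.uniform(0, 1, max(2, n // 2)), size=n)  # force ties
            labels = rng.random(n) > 0.5
            if labels.all() or not labels.any():
                continue
            auc, (fpr, tpr) = roc_auc(scores, labels)
            assert auc == pytest.approx(np.trapezoid(tpr, fpr), abs=1e-12)
            assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [True, True])


class TestIoU:
    def test_identical_masks(self):
        m = np.eye(5)
        assert iou(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4)); a[0, 0] = 1
        b = np.zeros((4, 4)); b[3, 3] = 1
        assert iou(a, b) == 0.0

    def test_offset_squares_third(self):
        a = np.zeros((4, 4)); a[1:3, 0:2] = 1
        b = np.zeros((4, 4)); b[1:3, 1:3] = 1
        assert iou(a, b) == pytest.approx(1 / 3)

    def test_empty_union_is_agreement(self):
        z = np.zeros((3, 3))
        assert iou(z, z) == 1.0

    def test_symmetry_and_bounds(self, rng):
        for _ in range(50):
            a = rng.random((8, 8)) > 0.5
            b = rng.random((8, 8)) > 0.5
            v = iou(a, b)
            assert v == iou(b, a)
            assert 0 <= v <= 1
            assert (v == 1.0) == np.array_equal(a, b)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            iou(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_median_over_truth_positive_images_only(self):
        full = np.ones((4, 4))
        empty = np.zeros((4, 4))
        # second pair (empty truth) must be excluded from the median
        v = median_iou([full, full], [full, empty])
        assert v == 1.0


class TestCohensKappa:
    def test_identical_nonconstant_ratings(self):
        assert cohens_kappa([0, 1, 0, 1], [0, 1, 0, 1]) == 1.0

    def test_handbook_table(self):
        # 2x2 agreement a=45, b=5, c=5, d=45 -> p_o=0.9, p_e=0.5 -> 0.8
        a = [1] * 50 + [0] * 50
        b = [1] * 45 + [0] * 5 + [1] * 5 + [0] * 45
        assert cohens_kappa(a, b) == pytest.approx(0.8)

    def test_independence_with_matched_marginals_is_zero(self):
        # rater B correct half the time in each class of A: p_o = p_e
        a = [1, 1, 0, 0]
        b = [1, 0, 1, 0]
        assert cohens_kappa(a, b) == pytest.approx(0.0)

    def test_constant_identical_raters_undefined(self):
        assert cohens_kappa([1, 1, 1], [1, 1, 1]) is None

    def test_relabeling_invariance(self, rng):
        a = rng.integers(0, 3, 60)
        b = rng.integers(0, 3, 60)
        perm = {0: 7, 1: 5, 2: 9}
        a2 = np.array([perm[x] for x in a])
        b2 = np.array([perm[x] for x in b])
        assert cohens_kappa(a, b) == pytest.approx(cohens_kappa(a2, b2))

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import cohen_kappa_score

        for _ in range(20):
            a = rng.integers(0, 2, 40)
            b = rng.integers(0, 2, 40)
            assert cohens_kappa(a, b) == pytest.approx(
                cohen_kappa_score(a, b), abs=1e-12)


def exhaustive_mcnemar(b, c):
    """Two-sided exact p by enumerating all 2^(b+c) discordant outcomes.

    Under H0 each discordant pair lands in cell b with probability 1/2;
    p = P(outcome at least as extreme as observed), doubling the smaller
    tail via |X - n/2| >= |b - n/2|."""
    n = b + c
    total = 0
    observed_dev = abs(b - n / 2)
    for x in range(2**n):
        k = bin(x).count("1")
        if abs(k - n / 2) >= observed_dev - 1e-12:
            total += 1
    return total / 2**n


class TestMcNemar:
    def test_symmetric_counts_give_one(self):
        assert mcnemar_test(7, 7, mode="exact") == 1.0

    def test_ten_zero_exact(self):
        assert mcnemar_test(10, 0, mode="exact") == pytest.approx(2 * 0.5**10)

    def test_two_nine_exact(self):
        assert mcnemar_test(2, 9, mode="exact") == pytest.approx(134 / 2048)

    def test_no_discordance_convention(self):
        assert mcnemar_test(0, 0) == 1.0

    @pytest.mark.parametrize("b,c", [(0, 5), (1, 4), (3, 3), (2, 9), (5, 7), (0, 12)])
    def test_exact_matches_exhaustive_enumeration(self, b, c):
        assert mcnemar_test(b, c, mode="exact") == pytest.approx(
            exhaustive_mcnemar(b, c))

    def test_matches_statsmodels_exact(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        table = [[30, 4], [9, 20]]
        p_mine = mcnemar_test(4, 9, mode="exact")
        p_sm = sm_mcnemar(table, exact=True).pvalue
        assert p_mine == pytest.approx(p_sm, abs=1e-10)

    def test_cc_chi2_large_counts(self):
        p = mcnemar_test(40, 60, mode="cc_chi2")
        expected = sps.chi2.sf((abs(40 - 60) - 1) ** 2 / 100, 1)
        assert p == pytest.approx(expected)

    def test_paired_classifier_comparison(self):
        truth = [1, 1, 1, 1, 0, 0, 0, 0]
        a = [1, 1, 1, 0, 0, 0, 0, 1]  # correct on 6 cases
        b = [1, 1, 0, 0, 0, 0, 1, 1]  # correct on 4 cases
        b_count, c_count, p = compare_paired_classifiers(a, b, truth)
        assert (b_count, c_count) == (2, 0)
        assert 0 < p <= 1


class TestBuildReport:
    def test_perfect_predictor(self):
        truth = [True] * 6 + [False] * 6
        report = build_report(truth, truth, scores=[1.0] * 6 + [0.0] * 6)
        assert report.accuracy.estimate == 1.0
        assert report.auc == 1.0

    def test_competition_row_with_wald_cis(self):
        pred = [True] * 114 + [False] * 6 + [True] * 6 + [False] * 74
        truth = [True] * 120 + [False] * 80
        report = build_report(pred, truth, ci_method="wald")
        assert round(report.accuracy.estimate, 3) == 0.940
        assert round(report.sensitivity.ci_low, 3) == 0.911
        assert round(report.sensitivity.ci_high, 3) == 0.989
        assert round(report.specificity.ci_low, 3) == 0.867
        assert round(report.specificity.ci_high, 3) == 0.983

    def test_stratified_counts_partition_pooled(self, rng):
        n = 100
        pred = rng.random(n) > 0.4
        truth = rng.random(n) > 0.5
        mods = np.where(rng.random(n) > 0.5, "WLI", "NBI")
        report = build_report(pred, truth, modalities=mods)
        pooled = report.counts
        parts = [report.strata[m].counts for m in ("WLI", "NBI")]
        assert sum(p.tp for p in parts) == pooled.tp
        assert sum(p.fp for p in parts) == pooled.fp
        assert sum(p.fn for p in parts) == pooled.fn
        assert sum(p.tn for p in parts) == pooled.tn

    def test_markdown_rendering(self):
        report = build_report([True, False], [True, False])
        md = report.to_markdown()
        assert "accuracy" in md and "1.000" in md
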