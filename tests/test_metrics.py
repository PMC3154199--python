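"""Windowed CCF/AUCCF, ROC/AUROC, operating point and cluster-robust
correlation, each against an independent oracle."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import infarctnet as inf


def pairwise_auroc(scores, labels):
    """Brute-force oracle: (concordant + half-tied pairs) / (n1 * n0)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestDiscretize:
    @pytest.mark.parametrize(
        "value,expected",
        [(0.049, 0), (0.05, 1), (3.0, 59), (0.0, 0), (2.999, 59)],
    )
    def test_bin_conventions(self, value, expected):
        assert inf.discretize(value) == expected

    def test_out_of_range_clipped(self):
        assert inf.discretize(3.4) == 59
        assert inf.discretize(-0.2) == 0


class TestCcf:
    def test_identical_lists(self):
        vals = np.linspace(0.1, 2.9, 20)
        assert inf.ccf(vals, vals) == 1.0

    def test_bin_aligned_mismatch_is_zero(self):
        gold = np.array([0.10, 0.50, 1.00])
        assert inf.ccf(gold + 0.2, gold) == 0.0

    def test_hand_binned_toy(self):
        # bins (0, 1, 2) vs (0, 2, 2) -> 2 of 3 match
        pred = [0.02, 0.06, 0.11]
        gold = [0.03, 0.12, 0.11]
        assert inf.ccf(pred, gold) == pytest.approx(2 / 3, abs=1e-12)

    def test_tolerance_rule(self):
        cfg = inf.EvaluationConfig(match_rule="tolerance")
        assert inf.ccf([1.0], [1.04], cfg) == 1.0
        assert inf.ccf([1.0], [1.06], cfg) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            inf.ccf([1.0, 2.0], [1.0])


class TestAuccf:
    def test_constant_curve_equals_height(self):
        assert inf.auccf(np.full(17, 0.8)) == pytest.approx(0.8, abs=1e-12)

    def test_linear_ramp(self):
        assert inf.auccf(np.linspace(0, 1, 11)) == pytest.approx(0.5, abs=1e-12)

    def test_three_point_trapezoid_by_hand(self):
        assert inf.auccf([0.5, 0.7, 0.9]) == pytest.approx(0.7, abs=1e-12)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            inf.auccf([0.5])


class TestRocCurve:
    def test_perfect_separation(self):
        roc = inf.roc_curve([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert roc.auroc == pytest.approx(1.0)

    def test_all_ties_give_chance(self):
        roc = inf.roc_curve([0.5] * 6, [0, 1, 0, 1, 0, 1])
        assert roc.auroc == pytest.approx(0.5)

    def test_textbook_four_sample_case(self):
        roc = inf.roc_curve([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert roc.auroc == pytest.approx(
            pairwise_auroc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]), abs=1e-12
        )
        assert roc.auroc == pytest.approx(0.75)

    def test_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(3)
        roc = inf.roc_curve(rng.normal(size=50), rng.integers(0, 2, 50))
        assert roc.fpf[0] == roc.tpf[0] == 0.0
        assert roc.fpf[-1] == roc.tpf[-1] == 1.0
        assert np.all(np.diff(roc.fpf) >= 0) and np.all(np.diff(roc.tpf) >= 0)

    @given(seed=st.integers(0, 500))
    def test_label_inversion_flips_area(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        a = inf.roc_curve(scores, labels).auroc
        b = inf.roc_curve(-scores, labels).auroc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(9)
        scores = np.round(rng.normal(size=200), 1)
        labels = rng.integers(0, 2, 200)
        assert inf.roc_curve(scores, labels).auroc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            inf.roc_curve([0.1, 0.2], [1, 1])


class TestOptimalPoint:
    def test_chance_diagonal(self):
        roc = inf.roc_curve([0.5] * 6, [0, 1, 0, 1, 0, 1])
        pt = inf.optimal_point(roc)
        assert pt.sensitivity == pytest.approx(0.5)
        assert pt.specificity == pytest.approx(0.5)

    def test_perfect_step(self):
        roc = inf.roc_curve([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        pt = inf.optimal_point(roc)
        assert pt.sensitivity == pytest.approx(1.0)
        assert pt.specificity == pytest.approx(1.0)

    def test_binormal_separation_two(self):
        # equal-variance binormal with d'=2: sensitivity = specificity =
        # standard normal CDF at 1 by symmetry
        z = np.linspace(8, -8, 4001)
        fpf = stats.norm.cdf(-z)
        tpf = stats.norm.cdf(2 - z)
        fpf[0], tpf[0], fpf[-1], tpf[-1] = 0, 0, 1, 1
        pt = inf.optimal_point(inf.RocCurve.from_points(fpf, tpf))
        expected = stats.norm.cdf(1)
        assert pt.sensitivity == pytest.approx(expected, abs=0.005)
        assert pt.specificity == pytest.approx(expected, abs=0.005)

    def test_sensitivity_equals_specificity_on_interpolated_point(self):
        rng = np.random.default_rng(11)
        roc = inf.roc_curve(rng.normal(size=80) + rng.integers(0, 2, 80),
                            rng.integers(0, 2, 80))
        pt = inf.optimal_point(roc)
        assert pt.sensitivity == pytest.approx(pt.specificity, abs=1e-12)


class TestConfusionFractions:
    def test_extreme_thresholds(self):
        scores = [0.2, 0.4, 0.6, 0.8]
        labels = [0, 0, 1, 1]
        assert inf.confusion_fractions(scores, labels, 0.0) == (1.0, 0.0, 1.0)
        assert inf.confusion_fractions(scores, labels, 1.0) == (0.0, 1.0, 0.0)

    def test_six_sample_enumeration(self):
        scores = np.array([0.1, 0.3, 0.45, 0.55, 0.7, 0.9])
        labels = np.array([0, 0, 1, 0, 1, 1])
        tpf, tnf, fpf = inf.confusion_fractions(scores, labels, 0.5)
        # by hand: positives 0.45/0.7/0.9 -> 2 of 3 above; negatives
        # 0.1/0.3/0.55 -> 1 of 3 above
        assert tpf == pytest.approx(2 / 3)
        assert fpf == pytest.approx(1 / 3)
        assert tnf == pytest.approx(2 / 3)
        assert tpf + (1 - tpf) == 1.0 and tnf + fpf == 1.0


class TestClusterCorrelation:
    def test_exact_linear_relation(self):
        rng = np.random.default_rng(0)
        pred = rng.uniform(0, 3, 60)
        clusters = np.repeat(np.arange(6), 10)
        res = inf.cluster_adjusted_correlation(pred, 2 * pred, clusters)
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)
        assert res.p_value < 1e-12  # below any reportable floor

    def test_null_has_small_correlation(self):
        rng = np.random.default_rng(42)
        pred = rng.normal(size=1000)
        gold = rng.normal(size=1000)
        clusters = np.repeat(np.arange(10), 100)
        res = inf.cluster_adjusted_correlation(pred, gold, clusters)
        assert abs(res.r) < 0.1
        assert res.p_value > 0.01

    def test_two_cluster_hand_sandwich(self):
        # 3 points per cluster, worked through the sandwich formula directly
        pred = np.array([1.0, 2.0, 3.0, 1.5, 2.5, 3.5])
        gold = np.array([1.1, 1.9, 3.2, 1.4, 2.8, 3.3])
        clusters = np.array([0, 0, 0, 1, 1, 1])
        X = np.column_stack([np.ones(6), pred])
        beta = np.linalg.solve(X.T @ X, X.T @ gold)
        e = gold - X @ beta
        meat = sum(
            np.outer(X[c == clusters].T @ e[c == clusters],
                     X[c == clusters].T @ e[c == clusters])
            for c in (0, 1)
        )
        cov = np.linalg.inv(X.T @ X) @ meat @ np.linalg.inv(X.T @ X)
        res = inf.cluster_adjusted_correlation(pred, gold, clusters)
        assert res.slope == pytest.approx(beta[1], abs=1e-12)
        assert res.se == pytest.approx(np.sqrt(cov[1, 1]), abs=1e-12)

    def test_matches_statsmodels_cluster_covariance(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        pred = rng.uniform(0, 3, 120)
        gold = 0.8 * pred + rng.normal(0, 0.4, 120)
        clusters = np.repeat(np.arange(8), 15)
        fit = sm.OLS(gold, sm.add_constant(pred)).fit(
            cov_type="cluster",
            cov_kwds={"groups": clusters, "use_correction": False},
            use_t=True,
        )
        res = inf.cluster_adjusted_correlation(pred, gold, clusters)
        assert res.slope == pytest.approx(fit.params[1], abs=1e-10)
        assert res.se == pytest.approx(fit.bse[1], abs=1e-10)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            inf.cluster_adjusted_correlation([1, 2], [1, 2], [0, 0])
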