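"""Closed-form checks of the clinical statistics toolkit."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from impedcyto.core import ConfigurationError
from impedcyto.clinstats import (
    bland_altman,
    boxplot_outliers,
    coefficient_of_variation,
    diagnose_threshold,
    linear_regression,
    roc_curve,
    sample_size_correlation,
)


def concordance_auc(scores, labels):
    """Brute-force Wilcoxon–Mann–Whitney AUC: P(score+ > score−) + ½ ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (pos.size * neg.size)


class TestRegression:
    def test_exact_line(self):
        r = linear_regression([1.0, 2.0, 3.0], [2.0, 4.0, 6.0])
        assert r.slope == pytest.approx(2.0)
        assert r.intercept == pytest.approx(0.0)
        assert r.r_squared == pytest.approx(1.0)

    def test_null_slope_p_uniform(self):
        """With y independent of x the slope p-value is ~Uniform(0,1)."""
        rng = np.random.default_rng(1)
        pvals = [
            linear_regression(rng.uniform(0, 1, 30), rng.uniform(0, 1, 30)).p_value
            for _ in range(300)
        ]
        # Kolmogorov-Smirnov against uniform at a generous level
        from scipy.stats import kstest

        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_degenerate_x_rejected(self):
        with pytest.raises(ConfigurationError):
            linear_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBlandAltman:
    def test_identical_vectors(self):
        r = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.bias == 0.0 and r.loa_low == 0.0 and r.loa_high == 0.0

    def test_constant_offset(self):
        m2 = np.array([1.0, 2.0, 3.0])
        r = bland_altman(m2 + 0.2, m2)
        assert r.bias == pytest.approx(0.2)
        assert r.loa_high - r.loa_low == pytest.approx(0.0, abs=1e-12)

    def test_loa_converges_to_196_sigma(self):
        """Differences ~ N(0, 0.25²), n = 10,000: LoA ≈ ±1.96·0.25 = ±0.49."""
        rng = np.random.default_rng(2)
        m2 = rng.uniform(0, 5, 10_000)
        r = bland_altman(m2 + 0.25 * rng.standard_normal(10_000), m2)
        assert r.loa_high == pytest.approx(1.96 * 0.25, rel=0.05)
        assert r.loa_low == pytest.approx(-1.96 * 0.25, rel=0.05)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            bland_altman([1.0], [1.0, 2.0])


class TestROC:
    def test_perfect_separation(self):
        assert roc_curve([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]).auc == 1.0

    def test_all_scores_equal(self):
        assert roc_curve([1, 1, 1, 1], [0, 1, 0, 1]).auc == pytest.approx(0.5)

    def test_worked_example(self):
        """Scores (0.1, 0.4, 0.35, 0.8) / labels (0,0,1,1): 3 of 4 concordant
        pairs → AUC 0.75."""
        assert roc_curve([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]).auc == pytest.approx(0.75)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_auc_equals_concordance(self, seed):
        """Trapezoid AUC equals brute-force pairwise concordance, ties included."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 200))
        scores = np.round(rng.uniform(0, 1, n), 2)  # rounding forces ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        r = roc_curve(scores, labels)
        assert r.auc == pytest.approx(concordance_auc(scores, labels), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        scores = rng.uniform(0, 1, 100)
        labels = rng.integers(0, 2, 100)
        labels[0], labels[1] = 0, 1
        a = roc_curve(scores, labels).auc
        b = roc_curve(np.exp(5 * scores), labels).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ConfigurationError):
            roc_curve([1.0, 2.0], [1, 1])


class TestPowerAnalysis:
    def test_rho_05(self):
        """ρ=0.5, α=0.05 two-tailed, power 0.8 → N = 29 (Fisher-z)."""
        spec = sample_size_correlation(0.5, 0.05, 0.8)
        assert spec.n_required == 29

    def test_rho_09_standard_formula(self):
        """ρ=0.9, α=0.01, power 0.9: Zα ≈ 2.58, Zβ ≈ 1.28, N = 10."""
        spec = sample_size_correlation(0.9, 0.01, 0.9)
        assert spec.z_alpha == pytest.approx(2.58, abs=0.005)
        assert spec.z_beta == pytest.approx(1.28, abs=0.005)
        assert spec.n_required == 10

    def test_near_perfect_correlation_floor(self):
        assert sample_size_correlation(0.9999, 0.01, 0.9).n_required == 4

    def test_invalid_rho_rejected(self):
        with pytest.raises(ConfigurationError):
            sample_size_correlation(1.5, 0.05, 0.8)


class TestCVAndOutliers:
    def test_cv_constant_zero(self):
        assert coefficient_of_variation([5.0, 5.0, 5.0]) == 0.0

    def test_cv_known_value(self):
        x = np.array([50.0, 150.0])  # mean 100, sd ~70.7
        assert coefficient_of_variation(x) == pytest.approx(70.71, abs=0.01)

    def test_cv_sampling_recovery(self):
        """Log-normal generator set to CV 62.88%: realized CV within 5%."""
        rng = np.random.default_rng(4)
        sigma = np.sqrt(np.log1p(0.6288**2))
        x = np.exp(rng.normal(np.log(100) - sigma**2 / 2, sigma, 10_000))
        assert coefficient_of_variation(x) == pytest.approx(62.88, rel=0.05)

    def test_outlier_fences(self):
        out = boxplot_outliers([1.0, 2.0, 3.0, 4.0, 100.0])
        assert list(out) == [100.0]

    def test_symmetric_outliers(self):
        x = np.concatenate([np.linspace(-1, 1, 20), [-50.0, 50.0]])
        out = boxplot_outliers(x)
        assert set(out) == {-50.0, 50.0}

    def test_all_equal_no_outliers(self):
        assert boxplot_outliers(np.ones(10)).size == 0


class TestDiagnosis:
    def test_boundary_is_negative(self):
        """Concentration exactly at the threshold is a negative call."""
        out = diagnose_threshold([11_000.0], threshold=11_000.0)
        assert not out["calls"][0]

    def test_disjoint_supports_perfect(self):
        conc = np.concatenate([np.full(50, 5000.0), np.full(50, 20_000.0)])
        labels = np.r_[np.zeros(50), np.ones(50)]
        out = diagnose_threshold(conc, labels, threshold=11_000.0)
        assert out["sensitivity"] == 1.0 and out["specificity"] == 1.0
        assert out["roc"].auc == 1.0

    def test_gaussian_auc_closed_form(self):
        """Overlapping Gaussian classes: AUC = Φ(Δ/(σ√2)) within 2%."""
        rng = np.random.default_rng(5)
        delta, sigma, n = 1.5, 1.0, 20_000
        conc = np.concatenate(
            [rng.normal(10, sigma, n), rng.normal(10 + delta, sigma, n)]
        )
        labels = np.r_[np.zeros(n), np.ones(n)]
        out = diagnose_threshold(conc, labels, threshold=10.0)
        expected = norm.cdf(delta / (sigma * np.sqrt(2)))
        assert out["roc"].auc == pytest.approx(expected, rel=0.02)

    def test_missing_labels_single_class_rejected(self):
        with pytest.raises(ConfigurationError):
            diagnose_threshold([1.0, 2.0], [1, 1], threshold=1.5)
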