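"""Statistical battery: frozen hand values, identities, calibration."""

import numpy as np
import pytest
from scipy import stats as sps

from cmrnorms import (
    anova_oneway,
    bartlett,
    chi_square_counts,
    ks_normality,
    multiple_regression,
    two_sample_t,
)
from cmrnorms.cohort_stats import StatsError
from cmrnorms.synthetic_cohort import Subject


def make_group(mean, sd, n, seed):
    """Sample with its empirical mean/SD forced to the stated summary."""
    x = np.random.default_rng(seed).normal(size=n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x


def make_subjects(sex, hr, age, bmi_w, outcome):
    # height fixed at 100 cm so bmi == weight numerically
    return [
        Subject(id=f"s{i}", scanner_label="t", sex=("male" if s else "female"),
                age=float(a), height=100.0, weight=float(w), heart_rate=float(h),
                global_value=float(y))
        for i, (s, h, a, w, y) in enumerate(zip(sex, hr, age, bmi_w, outcome))
    ]


class TestTwoSampleT:
    def test_welch_on_published_summaries(self):
        # (1173, 28, n=57) vs (1201, 25, n=35):
        # Welch t = -28 / sqrt(784/57 + 625/35) = -28/5.62241 = -4.98007
        a = make_group(1173, 28, 57, 1)
        b = make_group(1201, 25, 35, 2)
        res = two_sample_t(a, b, welch=True)
        assert res.statistic == pytest.approx(-4.98007, abs=1e-4)
        assert res.p_value < 1e-4

    def test_identical_groups_p_one(self):
        res = two_sample_t([5.0] * 10, [5.0] * 10)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_swapping_groups_flips_sign(self):
        a, b = make_group(10, 2, 12, 3), make_group(12, 3, 15, 4)
        r1, r2 = two_sample_t(a, b), two_sample_t(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_pooled_matches_scipy(self):
        a, b = make_group(10, 2, 12, 5), make_group(11, 2, 15, 6)
        res = two_sample_t(a, b, welch=False)
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert res.statistic == pytest.approx(float(ref.statistic))

    def test_tiny_groups_rejected(self):
        with pytest.raises(StatsError):
            two_sample_t([1.0], [1.0, 2.0])


class TestAnovaBartlettChi2:
    def test_two_group_anova_equals_squared_pooled_t(self):
        a, b = make_group(10, 2, 12, 7), make_group(11, 3, 15, 8)
        f = anova_oneway([a, b])
        t = two_sample_t(a, b, welch=False)
        assert f.statistic == pytest.approx(t.statistic**2)
        assert f.p_value == pytest.approx(t.p_value)
        assert f.df == (1, 25)

    def test_bartlett_null_calibration(self):
        # equal-variance groups: p-values roughly uniform under the null
        rng = np.random.default_rng(10)
        pvals = []
        for _ in range(1000):
            groups = [rng.normal(0, 1, 30) for _ in range(3)]
            pvals.append(bartlett(groups).p_value)
        frac = np.mean(np.asarray(pvals) < 0.05)
        assert 0.025 <= frac <= 0.08
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_balanced_counts_chi_square(self):
        res = chi_square_counts([25, 25])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_chi_square_against_explicit_expected(self):
        res = chi_square_counts([57, 35], [46, 46])
        ref = sps.chisquare([57, 35], [46, 46])
        assert res.p_value == pytest.approx(float(ref.pvalue))


class TestNormality:
    def test_gaussian_sample_not_rejected(self):
        x = np.random.default_rng(11).normal(1173, 28, 200)
        assert ks_normality(x).p_value > 0.05
        assert ks_normality(x, method="ks").p_value > 0.05

    def test_skewed_sample_rejected(self):
        x = np.random.default_rng(12).exponential(1.0, 200)
        assert ks_normality(x).p_value < 0.05

    def test_zero_variance_rejected(self):
        with pytest.raises(StatsError):
            ks_normality([1.0] * 10)


class TestMultipleRegression:
    def test_exact_linear_outcome_recovered(self):
        rng = np.random.default_rng(13)
        n = 40
        sex = rng.integers(0, 2, n)
        hr = rng.normal(60, 10, n)
        age = rng.normal(40, 10, n)
        w = rng.normal(24, 3, n)
        y = 1000.0 - 38.834 * sex + 0.672 * hr + 0.0 * age + 0.0 * w
        reg = multiple_regression(make_subjects(sex, hr, age, w, y))
        assert reg.coefficients["sex"][0] == pytest.approx(-38.834, abs=1e-8)
        assert reg.coefficients["heart_rate"][0] == pytest.approx(0.672, abs=1e-8)
        assert reg.coefficients["age"][0] == pytest.approx(0.0, abs=1e-8)
        assert reg.intercept == pytest.approx(1000.0, abs=1e-6)

    def test_constant_outcome_gives_zero_betas(self):
        rng = np.random.default_rng(14)
        n = 30
        reg = multiple_regression(make_subjects(
            rng.integers(0, 2, n), rng.normal(60, 10, n),
            rng.normal(40, 10, n), rng.normal(24, 3, n), np.full(n, 1000.0)))
        for beta, _ in reg.coefficients.values():
            assert beta == pytest.approx(0.0, abs=1e-9)
        assert reg.intercept == pytest.approx(1000.0)

    def test_residuals_orthogonal_to_covariates(self):
        rng = np.random.default_rng(15)
        n = 60
        sex = rng.integers(0, 2, n)
        hr = rng.normal(60, 10, n)
        age = rng.normal(40, 10, n)
        w = rng.normal(24, 3, n)
        y = 1100 - 30 * sex + 0.8 * hr + rng.normal(0, 15, n)
        subs = make_subjects(sex, hr, age, w, y)
        reg = multiple_regression(subs)
        pred = reg.intercept + sum(
            reg.coefficients[c][0] * np.array(v)
            for c, v in [("sex", sex), ("heart_rate", hr), ("age", age), ("bmi", w)]
        )
        resid = y - pred
        for v in (sex, hr, age, w):
            assert abs(resid @ (v - v.mean())) < 1e-6 * n * np.std(y)

    def test_collinear_covariates_reported(self):
        rng = np.random.default_rng(16)
        n = 30
        hr = rng.normal(60, 10, n)
        with pytest.raises(StatsError, match="age~bmi|collinear|constant"):
            multiple_regression(make_subjects(
                rng.integers(0, 2, n), hr, hr, hr, rng.normal(1100, 20, n)))

    def test_constant_covariate_reported(self):
        rng = np.random.default_rng(17)
        n = 30
        with pytest.raises(StatsError, match="sex"):
            multiple_regression(make_subjects(
                np.ones(n), rng.normal(60, 10, n), rng.normal(40, 10, n),
                rng.normal(24, 3, n), rng.normal(1100, 20, n)))

    def test_sex_null_type_i_error_calibrated(self):
        # no true sex effect: rejection rate at alpha 0.05 in [0.03, 0.07]
        rng = np.random.default_rng(18)
        n = 50
        rejections = 0
        reps = 2000
        for _ in range(reps):
            sex = np.concatenate([np.ones(25), np.zeros(25)])
            hr = rng.normal(60, 10, n)
            age = rng.normal(40, 10, n)
            w = rng.normal(24, 3, n)
            y = 1100 + 0.8 * hr + rng.normal(0, 20, n)
            reg = multiple_regression(make_subjects(sex, hr, age, w, y))
            rejections += reg.coefficients["sex"][1] < 0.05
        assert 0.03 <= rejections / reps <= 0.07
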