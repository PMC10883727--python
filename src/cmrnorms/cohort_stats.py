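"""Cohort-level statistical battery.

Normality checks, two-sample comparisons, one-way ANOVA, variance
homogeneity, count chi-square, and the multiple regression of global
mapping values on sex, heart rate, age and BMI. Thin, typed wrappers
over scipy.stats and statsmodels with the conventions used throughout
this package made explicit (sex coded male = 1, female = 0; two-tailed
p-values; Welch t by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .synthetic_cohort import Subject

__all__ = [
    "TestResult",
    "RegressionResult",
    "StatsError",
    "two_sample_t",
    "multiple_regression",
    "ks_normality",
    "anova_oneway",
    "bartlett",
    "chi_square_counts",
]

#: Covariate coding used by :func:`multiple_regression`. With male = 1,
#: a negative sex coefficient means females have *higher* values.
COVARIATE_UNITS = {
    "sex": "male indicator (female = 0, male = 1), ms per unit",
    "heart_rate": "beats/min, ms per beat/min",
    "age": "years, ms per year",
    "bmi": "kg/m^2, ms per kg/m^2",
}


class StatsError(ValueError):
    """Raised for degenerate inputs the test formulas cannot handle."""


@dataclass
class TestResult:
    statistic: float
    p_value: float
    test_name: str
    df: float | tuple[float, ...] | None = None


@dataclass
class RegressionResult:
    """OLS fit of an outcome on {sex, heart rate, age, BMI}.

    ``coefficients`` maps covariate name to ``(beta, p_value)`` with
    two-tailed p from the t distribution; units per ``covariate_units``.
    """

    coefficients: dict[str, tuple[float, float]]
    intercept: float
    n: int
    covariate_units: dict[str, str] = field(default_factory=lambda: dict(COVARIATE_UNITS))
    conf_int: dict[str, tuple[float, float]] = field(default_factory=dict)


def two_sample_t(
    group_a: Sequence[float], group_b: Sequence[float], welch: bool = True
) -> TestResult:
    """Unpaired two-sample t-test, two-tailed.

    Welch (unequal variances) by default; ``welch=False`` uses the
    pooled-variance test. Degenerate input (both groups zero-variance
    with equal means) returns statistic 0, p = 1 by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatsError("each group needs n >= 2")
    name = "welch_t" if welch else "pooled_t"
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        return TestResult(0.0, 1.0, name, float(a.size + b.size - 2))
    res = sps.ttest_ind(a, b, equal_var=not welch)
    return TestResult(float(res.statistic), float(res.pvalue), name, float(res.df))


def _design_matrix(subjects: Sequence[Subject]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sex": [1.0 if s.sex == "male" else 0.0 for s in subjects],
            "heart_rate": [s.heart_rate for s in subjects],
            "age": [s.age for s in subjects],
            "bmi": [s.bmi for s in subjects],
        }
    )


def multiple_regression(
    subjects: Sequence[Subject], outcome: str = "global_value"
) -> RegressionResult:
    """OLS of a per-subject outcome on sex, heart rate, age and BMI.

    Sex is coded male = 1, female = 0, so the sex coefficient is
    negative when females have higher mapping values. Raises
    :class:`StatsError` on rank deficiency, naming the collinear
    covariates.
    """
    y = np.asarray([getattr(s, outcome) for s in subjects], dtype=float)
    if np.any(np.isnan(y)):
        raise StatsError(f"outcome {outcome!r} missing for some subjects")
    X = _design_matrix(subjects)
    n, p = X.shape
    if n <= p + 1:
        raise StatsError(f"need n > {p + 1} subjects, got {n}")
    constant = [c for c in X.columns if X[c].nunique() == 1]
    if constant:
        raise StatsError(f"constant covariates: {constant}")
    Xc = sm.add_constant(X)
    if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
        corr = X.corr().abs()
        pairs = [
            f"{a}~{b}"
            for i, a in enumerate(X.columns)
            for b in X.columns[i + 1 :]
            if corr.loc[a, b] > 1 - 1e-10
        ]
        raise StatsError(f"rank-deficient design; collinear covariates: {pairs or 'unknown'}")
    fit = sm.OLS(y, Xc).fit()
    ci = fit.conf_int()
    return RegressionResult(
        coefficients={
            c: (float(fit.params[c]), float(fit.pvalues[c])) for c in X.columns
        },
        intercept=float(fit.params["const"]),
        n=n,
        conf_int={c: (float(ci.loc[c, 0]), float(ci.loc[c, 1])) for c in X.columns},
    )


def ks_normality(values: Sequence[float], method: str = "lilliefors") -> TestResult:
    """Kolmogorov-Smirnov-type test of normality.

    ``method="lilliefors"`` (default) uses the Lilliefors correction,
    appropriate when mean and SD are estimated from the sample.
    ``method="ks"`` is the classical one-sample KS test against a
    normal with the sample's own mean/SD; its p-value is conservative
    with estimated parameters.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise StatsError("need n >= 4 for a normality test")
    if x.std(ddof=1) == 0:
        raise StatsError("zero-variance sample")
    if method == "lilliefors":
        from statsmodels.stats.diagnostic import lilliefors

        stat, p = lilliefors(x, dist="norm")
        return TestResult(float(stat), float(p), "lilliefors")
    if method == "ks":
        res = sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
        return TestResult(float(res.statistic), float(res.pvalue), "kolmogorov_smirnov")
    raise ValueError(f"unknown method {method!r}")


def anova_oneway(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way ANOVA across two or more groups."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise StatsError("need >= 2 groups with n >= 2 each")
    res = sps.f_oneway(*gs)
    k = len(gs)
    n = sum(g.size for g in gs)
    return TestResult(float(res.statistic), float(res.pvalue), "anova_oneway", (k - 1, n - k))


def bartlett(groups: Sequence[Sequence[float]]) -> TestResult:
    """Bartlett's test of variance homogeneity across groups."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise StatsError("need >= 2 groups with n >= 2 each")
    res = sps.bartlett(*gs)
    return TestResult(float(res.statistic), float(res.pvalue), "bartlett", len(gs) - 1)


def chi_square_counts(
    observed: Sequence[float], expected: Sequence[float] | None = None
) -> TestResult:
    """Chi-square goodness-of-fit on counts (default: uniform expected)."""
    obs = np.asarray(observed, dtype=float)
    if obs.size < 2:
        raise StatsError("need >= 2 categories")
    exp = None if expected is None else np.asarray(expected, dtype=float)
    res = sps.chisquare(obs, exp)
    return TestResult(float(res.statistic), float(res.pvalue), "chi_square", obs.size - 1)
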