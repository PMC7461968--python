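"""Cohort statistics: normality, paired comparisons, and age trends.

The analysis treats each subject's per-nucleus ROI mean susceptibility
as one observation.  Normality is screened with the one-sample
Kolmogorov-Smirnov statistic against a normal law with sample-estimated
mean/SD; because the parameters are estimated, the p-value uses the
Lilliefors correction.  Nuclei are compared pairwise with a paired
t-test, the susceptibility-age association is summarized by the Pearson
correlation, and the age trend chi(age) = slope*age + intercept is fit
by ordinary least squares with the adjusted R^2
1 - (1 - R^2)(n - 1)/(n - 2) reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "AgeTrendFit",
    "PairedTestResult",
    "pearson_with_age",
    "fit_age_trend",
    "paired_t",
    "ks_normality",
]


@dataclass
class AgeTrendFit:
    """OLS line of mean ROI susceptibility versus age for one nucleus."""

    nucleus: str
    slope: float  # ppm / year
    intercept: float  # ppm
    adj_r2: float
    rho: float
    p_value: float
    n: int


@dataclass
class PairedTestResult:
    pair: tuple[str, str]
    t_stat: float
    p_value: float
    n: int


def pearson_with_age(means, ages) -> tuple[float, float]:
    """Pearson correlation between per-subject ROI means and ages.

    Returns (rho, two-sided p) with p from the t transform on n - 2
    degrees of freedom.  Requires n >= 3 and non-degenerate variance in
    both vectors.
    """
    x = np.asarray(ages, dtype=np.float64)
    y = np.asarray(means, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("correlation undefined for a zero-variance vector")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def fit_age_trend(means, ages, nucleus: str = "") -> AgeTrendFit:
    """Least-squares line of susceptibility versus age with adjusted R^2."""
    x = np.asarray(ages, dtype=np.float64)
    y = np.asarray(means, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.var(x) == 0:
        raise ValueError("constant ages give a singular design")
    n = x.size
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    if np.var(y) == 0:
        rho, p = 0.0, 1.0
    else:
        rho, p = pearson_with_age(y, x)
    return AgeTrendFit(
        nucleus=nucleus,
        slope=float(slope),
        intercept=float(intercept),
        adj_r2=float(adj_r2),
        rho=rho,
        p_value=p,
        n=int(n),
    )


def paired_t(x, y, pair: tuple[str, str] = ("", "")) -> PairedTestResult:
    """Two-sided paired-samples t-test (df = n - 1, sample SD)."""
    a = np.asarray(x, dtype=np.float64)
    b = np.asarray(y, dtype=np.float64)
    if a.size != b.size or a.size < 2:
        raise ValueError("paired test needs equal-length vectors with n >= 2")
    d = a - b
    if np.var(d, ddof=1) == 0:
        raise ValueError("zero variance of the paired differences; test degenerate")
    res = sps.ttest_rel(a, b)
    return PairedTestResult(pair=pair, t_stat=float(res.statistic), p_value=float(res.pvalue), n=int(a.size))


def ks_normality(x) -> tuple[float, float]:
    """One-sample KS normality check with sample-estimated parameters.

    The statistic is sup |F_n - Phi((x - mean)/sd)|, in [0, 1]; the
    p-value uses the Lilliefors correction, which is required when the
    normal parameters are estimated from the same sample (the naive KS
    p-value would be badly conservative).
    """
    a = np.asarray(x, dtype=np.float64)
    if a.size < 4:
        raise ValueError("KS normality test needs n >= 4")
    stat, p = lilliefors(a, dist="norm", pvalmethod="table")
    return float(stat), float(p)
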