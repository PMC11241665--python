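"""Two-group comparison with a normality gate.

Each metric is compared between the sham and BBBd cohorts the same way
throughout: both groups are checked for normality with a Kolmogorov-Smirnov
test against a normal with estimated mean/sd (Lilliefors correction); if both
pass, a pooled-variance two-sample Student's t-test is used, otherwise a
two-sided Mann-Whitney U test.  Groups are reported as median [Q1, Q3].

The Mann-Whitney implementation is exact (full null distribution of U via
the standard counting recursion) for small tie-free samples and falls back
to the tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "GroupComparison",
    "ks_normality",
    "mann_whitney",
    "students_t",
    "compare_groups",
]

ALPHA = 0.05
EXACT_MAX_N = 16  # exact U distribution when n_x + n_y <= this and no ties


def ks_normality(sample: np.ndarray) -> float:
    """Lilliefors-corrected KS p-value for normality; needs n >= 5.

    A constant sample is non-normal by convention (p = 0).
    """
    x = np.asarray(sample, float)
    if x.size < 5:
        raise ValueError("normality test needs n >= 5")
    if np.ptp(x) == 0:
        return 0.0
    _stat, p = lilliefors(x, dist="norm", pvalmethod="table")
    return float(p)


@lru_cache(maxsize=None)
def _u_counts(n: int, m: int) -> tuple[int, ...]:
    """Number of rank arrangements with each U value, for group sizes n, m.

    Recursion: f(n, m, u) = f(n-1, m, u-m) + f(n, m-1, u); counts sum to
    C(n+m, n).
    """
    if n == 0 or m == 0:
        return (1,)
    a = _u_counts(n - 1, m)  # last element from group x: adds m to U? see below
    b = _u_counts(n, m - 1)
    size = n * m + 1
    out = [0] * size
    for u, c in enumerate(a):
        out[u + m] += c
    for u, c in enumerate(b):
        out[u] += c
    return tuple(out)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U of group x: number of (x_i, y_j) pairs with x_i > y_j (ties 0.5)."""
    diff = x[:, None] - y[None, :]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


def mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of x, p).

    Exact tail enumeration when the pooled sample is small (<= 16) and
    tie-free; otherwise the normal approximation with tie correction and
    continuity correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n, m = x.size, y.size
    if n < 3 or m < 3:
        raise ValueError("both groups need n >= 3")
    u = _u_statistic(x, y)
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size

    if n + m <= EXACT_MAX_N and not has_ties:
        counts = _u_counts(n, m)
        total = math.comb(n + m, n)
        u_low = min(u, n * m - u)
        tail = sum(c for uu, c in enumerate(counts) if uu <= u_low)
        p = min(1.0, 2.0 * tail / total)
        return u, p

    mu = n * m / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    nm = n + m
    sigma2 = n * m / 12.0 * ((nm + 1) - tie_term / (nm * (nm - 1)))
    if sigma2 <= 0:
        return u, 1.0
    z = (abs(u - mu) - 0.5) / math.sqrt(sigma2)
    p = min(1.0, 2.0 * _norm_sf(max(z, 0.0)))
    return u, p


def _norm_sf(z: float) -> float:
    return 0.5 * math.erfc(z / math.sqrt(2.0))


def students_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided pooled-variance two-sample t-test; returns (t, p)."""
    from scipy import stats as sps

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n, m = x.size, y.size
    if n < 3 or m < 3:
        raise ValueError("both groups need n >= 3")
    sp2 = (((n - 1) * np.var(x, ddof=1) + (m - 1) * np.var(y, ddof=1))
           / (n + m - 2))
    if sp2 == 0:
        return (0.0, 1.0) if np.mean(x) == np.mean(y) else (math.inf, 0.0)
    t = float((np.mean(x) - np.mean(y)) / math.sqrt(sp2 * (1 / n + 1 / m)))
    p = float(2.0 * sps.t.sf(abs(t), df=n + m - 2))
    return t, p


@dataclass
class GroupComparison:
    """Result of one metric's sham-vs-BBBd comparison."""

    metric: str
    values_a: np.ndarray
    values_b: np.ndarray
    median_a: float
    q1_a: float
    q3_a: float
    median_b: float
    q1_b: float
    q3_b: float
    normality_p_a: float
    normality_p_b: float
    test: str            # "t" or "MW"
    statistic: float
    p_value: float
    significant: bool

    def summary(self) -> str:
        iqr_a = self.q3_a - self.q1_a
        iqr_b = self.q3_b - self.q1_b
        star = " *" if self.significant else ""
        return (f"{self.metric}: {self.median_a:.3g} [{iqr_a:.3g}] vs "
                f"{self.median_b:.3g} [{iqr_b:.3g}], {self.test}, "
                f"p = {self.p_value:.4g}{star}")


def _quartiles(x: np.ndarray) -> tuple[float, float, float]:
    """(median, Q1, Q3) with linear interpolation."""
    q1, med, q3 = np.percentile(x, [25, 50, 75], method="linear")
    return float(med), float(q1), float(q3)


def compare_groups(metric: str, values_a: np.ndarray, values_b: np.ndarray,
                   alpha: float = ALPHA) -> GroupComparison:
    """Normality-gated two-group comparison with median [IQR] reporting.

    Student's t (pooled) is used iff *both* groups pass the Lilliefors
    normality check at ``alpha``; otherwise Mann-Whitney.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 5 or b.size < 5:
        raise ValueError("both groups need n >= 5")
    p_norm_a = ks_normality(a)
    p_norm_b = ks_normality(b)
    if p_norm_a > alpha and p_norm_b > alpha:
        test = "t"
        stat, p = students_t(a, b)
    else:
        test = "MW"
        stat, p = mann_whitney(a, b)
    med_a, q1_a, q3_a = _quartiles(a)
    med_b, q1_b, q3_b = _quartiles(b)
    return GroupComparison(
        metric=metric, values_a=a, values_b=b,
        median_a=med_a, q1_a=q1_a, q3_a=q3_a,
        median_b=med_b, q1_b=q1_b, q3_b=q3_b,
        normality_p_a=p_norm_a, normality_p_b=p_norm_b,
        test=test, statistic=stat, p_value=p,
        significant=bool(p < alpha))
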