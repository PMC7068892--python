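"""Agreement and association statistics for modality comparison.

Bland-Altman percent bias with 95% limits of agreement, two-way-random
absolute-agreement single-measure intraclass correlation (ICC(2,1)),
Spearman rank correlation with the poor/moderate/strong/very-strong
grading bands, and the D'Agostino-Pearson omnibus K2 normality test.

The Bland-Altman convention is test-minus-reference: for paired series
``a`` (reference) and ``b`` (test), each percent difference is
``100 * (b_i - a_i) / ((a_i + b_i) / 2)``; the bias is their mean and
the limits of agreement bias +/- 1.96 sample SD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats as sps

__all__ = [
    "BlandAltmanReport",
    "IccReport",
    "CorrelationReport",
    "bland_altman_percent",
    "icc_single",
    "spearman",
    "dagostino_k2",
    "grade_correlation",
]

LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class BlandAltmanReport:
    """Percent-difference agreement between a test and a reference series."""

    diffs: np.ndarray
    bias: float
    loa_low: float
    loa_high: float
    n: int

    def __post_init__(self):
        if not (self.loa_low <= self.bias + 1e-12 and self.bias <= self.loa_high + 1e-12):
            raise ValueError("limits of agreement must bracket the bias")


@dataclass(frozen=True)
class IccReport:
    """Single-measure two-way-random absolute-agreement ICC with its ANOVA mean squares."""

    icc: float
    ms_rows: float
    ms_cols: float
    ms_error: float
    n: int
    k: int

    def __post_init__(self):
        if self.icc > 1 + 1e-12:
            raise ValueError("ICC cannot exceed 1")
        if self.n < 2 or self.k < 2:
            raise ValueError("ICC needs at least 2 subjects and 2 raters")


@dataclass(frozen=True)
class CorrelationReport:
    """Spearman rho with p-value and the printed-band verbal grade."""

    rho: float
    p_value: float
    grade: str | None
    n: int


def bland_altman_percent(a, b) -> BlandAltmanReport:
    """Bland-Altman percent differences of test series ``b`` vs reference ``a``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    if a.size < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    avg = 0.5 * (a + b)
    zero = np.flatnonzero(avg == 0.0)
    if zero.size:
        raise ValueError(f"pair {int(zero[0])} has zero average; percent difference undefined")
    d = 100.0 * (b - a) / avg
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanReport(
        diffs=d, bias=bias,
        loa_low=bias - LOA_MULTIPLIER * sd,
        loa_high=bias + LOA_MULTIPLIER * sd,
        n=int(a.size),
    )


def icc_single(measurements) -> IccReport:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``measurements`` is an ``n x k`` table (subjects x raters) with no
    missing cells.  The estimator is built from the two-way ANOVA mean
    squares::

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    Negative estimates are reported as computed.
    """
    x = np.asarray(measurements, dtype=float)
    if x.ndim != 2:
        raise ValueError("measurements must be an n x k table")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError(f"need at least 2 subjects and 2 raters, got {n} x {k}")
    if np.any(~np.isfinite(x)):
        raise ValueError("missing or non-finite cells are not allowed (no imputation)")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    resid = x - row_means[:, None] - col_means[None, :] + grand
    ss_err = float(np.sum(resid**2))
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    icc = (msr - mse) / denom if denom != 0 else 1.0
    return IccReport(icc=float(icc), ms_rows=msr, ms_cols=msc, ms_error=mse, n=n, k=k)


def grade_correlation(rho: float) -> str:
    """Verbal grade of |rho|: boundaries 0.5/0.7/0.9 belong to the higher band."""
    r = abs(rho)
    if r >= 0.9:
        return "very strong"
    if r >= 0.7:
        return "strong"
    if r >= 0.5:
        return "moderate"
    return "poor"


def _exact_permutation_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact p by enumerating all pairings of the rank vectors."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    count = 0
    total = 0
    tol = 1e-12
    for perm in permutations(ry):
        r = float(np.dot(rx, np.asarray(perm) - ry.mean())) / (x.size * ry.std())
        count += abs(r) >= abs(rho_obs) - tol
        total += 1
    return count / total


def spearman(x, y) -> CorrelationReport:
    """Spearman rank correlation with tie-averaged ranks.

    p-value by the t approximation for n >= 10 and by exhaustive
    permutation below; constant input yields a missing (NaN) rho.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    n = x.size
    if n < 3:
        raise ValueError("Spearman correlation needs at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationReport(rho=float("nan"), p_value=float("nan"), grade=None, n=n)
    rho, p_t = sps.spearmanr(x, y)
    rho = float(rho)
    if n < 10:
        p = _exact_permutation_p(x, y, rho)
    else:
        p = float(p_t)
    return CorrelationReport(rho=rho, p_value=p, grade=grade_correlation(rho), n=n)


def dagostino_k2(x) -> tuple[float, float]:
    """D'Agostino-Pearson omnibus K2 normality test.

    ``K2 = z_skew^2 + z_kurt^2`` referred to chi-square with 2 df.  The
    standardizing transformations are asymptotic, so samples below
    n = 20 are refused.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 20:
        raise ValueError(
            f"D'Agostino-Pearson K2 needs n >= 20 (got {x.size}); "
            "collect more data or use a small-sample normality test"
        )
    stat, p = sps.normaltest(x)
    return float(stat), float(p)
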