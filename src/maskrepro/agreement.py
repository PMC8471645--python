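"""Agreement and reproducibility statistics for paired measurements.

Implements the statistical toolkit for a two-scan repeatability study:

* Dice similarity coefficient between two masks;
* the two-way random-effects, single-measurement, absolute-agreement
  intraclass correlation ICC(2,1) with its 95% confidence interval
  (Shrout-Fleiss / McGraw-Wong F-based bounds);
* significance of ICC differences by confidence-interval overlap;
* paired Wilcoxon signed-rank tests with Benjamini-Hochberg correction;
* Spearman rank correlation;
* Bland-Altman bias and limits of agreement;
* the median inter-scan percentage difference.

The ICC point estimate follows the two-way ANOVA decomposition: with mean
squares MSR (rows/subjects), MSC (columns/conditions) and MSE (residual),

    ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .mask_io import BinaryMask, _check_same_grid

__all__ = [
    "MeasurementTable",
    "ICCResult",
    "BlandAltmanResult",
    "dsc",
    "icc_two_way_random_single",
    "icc_point",
    "icc_point_batch",
    "ci_overlap_significant",
    "wilcoxon_signed_rank",
    "bh_adjust",
    "spearman",
    "bland_altman",
    "percent_median_difference",
]

_DEGENERATE_TOL = 1e-12


@dataclass(frozen=True)
class MeasurementTable:
    """An n x k table of one feature measured under k repeated conditions."""

    values: np.ndarray
    feature_name: str = ""
    method_id: str = ""
    region: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("measurement table must be 2D (subjects x conditions)")
        object.__setattr__(self, "values", v)

    def complete_cases(self) -> np.ndarray:
        """Rows without missing values (single-score ICC needs a full table)."""
        v = self.values
        return v[~np.isnan(v).any(axis=1)]


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    n_subjects: int
    k_conditions: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.icc + 1e-12 and self.icc <= self.ci_high + 1e-12):
            raise ValueError("confidence interval must bracket the point estimate")


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    n: int


def dsc(a: BinaryMask, b: BinaryMask) -> float:
    """Dice similarity coefficient 2|A^B| / (|A|+|B|)."""
    _check_same_grid(a, b)
    na, nb = a.count, b.count
    if na + nb == 0:
        raise ValueError("DSC undefined for two empty masks")
    inter = int(np.count_nonzero(a.voxels & b.voxels))
    return 2.0 * inter / (na + nb)


def _anova_mean_squares(values: np.ndarray) -> tuple[float, float, float, int, int]:
    n, k = values.shape
    grand = values.mean()
    row_means = values.mean(axis=1)
    col_means = values.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sst = float(((values - grand) ** 2).sum())
    sse = max(sst - ssr - ssc, 0.0)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return msr, msc, mse, n, k


def icc_point(values: np.ndarray) -> float:
    """ICC(2,1) point estimate for a complete n x k table."""
    values = np.asarray(values, dtype=float)
    if np.all(values == values[:, [0]]):  # exact column agreement
        return 1.0
    msr, msc, mse, n, k = _anova_mean_squares(values)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if abs(denom) < _DEGENERATE_TOL:
        return 1.0
    return (msr - mse) / denom


def icc_point_batch(values: np.ndarray, keep_indices: np.ndarray) -> np.ndarray:
    """Vectorized ICC(2,1) over row subsets of one table.

    ``keep_indices`` has shape (runs, m): each row selects the m subjects kept
    in that run.  Used by the permutation test, where thousands of subset
    ICCs are needed.
    """
    values = np.asarray(values, dtype=float)
    sub = values[keep_indices]  # (runs, m, k)
    runs, m, k = sub.shape
    grand = sub.mean(axis=(1, 2), keepdims=True)
    row_means = sub.mean(axis=2, keepdims=True)
    col_means = sub.mean(axis=1, keepdims=True)
    ssr = k * ((row_means - grand) ** 2).sum(axis=(1, 2))
    ssc = m * ((col_means - grand) ** 2).sum(axis=(1, 2))
    sst = ((sub - grand) ** 2).sum(axis=(1, 2))
    sse = np.clip(sst - ssr - ssc, 0.0, None)
    msr = ssr / (m - 1)
    msc = ssc / (k - 1)
    mse = sse / ((m - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / m) * (msc - mse)
    out = np.ones(runs)
    ok = np.abs(denom) >= _DEGENERATE_TOL
    out[ok] = (msr[ok] - mse[ok]) / denom[ok]
    return out


def icc_two_way_random_single(
    table: MeasurementTable | np.ndarray, alpha: float = 0.05
) -> ICCResult:
    """ICC(2,1) with the F-based 100(1-alpha)% confidence interval.

    Rows with missing values are dropped (complete-case).  A table with zero
    total variance has perfect agreement by convention: ICC = 1 with the
    degenerate interval [1, 1] and a warning.
    """
    if not isinstance(table, MeasurementTable):
        table = MeasurementTable(table)
    values = table.complete_cases()
    n, k = values.shape
    if n < 3:
        raise ValueError(f"ICC needs >= 3 complete cases, got {n}")
    if k < 2:
        raise ValueError("ICC needs >= 2 conditions")
    msr, msc, mse, n, k = _anova_mean_squares(values)
    scale = max(abs(values).max(), 1.0)
    if (msr + msc + mse) <= _DEGENERATE_TOL * scale**2:
        warnings.warn("zero total variance: ICC degenerate, defined as 1")
        return ICCResult(1.0, 1.0, 1.0, n, k)
    if np.all(values == values[:, [0]]):  # exact column agreement
        return ICCResult(1.0, 1.0, 1.0, n, k)
    icc = icc_point(values)

    if 1.0 - icc < 1e-12 or mse <= _DEGENERATE_TOL * scale**2:
        # perfect (or numerically perfect) agreement: interval collapses
        lo, hi = icc, 1.0
        return ICCResult(float(np.clip(icc, -1, 1)), float(np.clip(lo, -1, 1)), hi, n, k)

    # Satterthwaite df and F bounds (McGraw & Wong, absolute agreement)
    a = k * icc / (n * (1.0 - icc))
    b = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc))
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lo = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
    hi = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
    icc = float(np.clip(icc, -1.0, 1.0))
    lo = float(np.clip(min(lo, icc), -1.0, 1.0))
    hi = float(np.clip(max(hi, icc), -1.0, 1.0))
    return ICCResult(icc, lo, hi, n, k)


def ci_overlap_significant(a: ICCResult, b: ICCResult) -> bool:
    """True (significantly different) iff the two 95% CIs are disjoint.

    Intervals sharing exactly one endpoint count as overlapping, the
    conservative reading.
    """
    return a.ci_high < b.ci_low or b.ci_high < a.ci_low


def wilcoxon_signed_rank(x, y) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Zero differences are dropped before ranking (classical Wilcoxon, not the
    Pratt variant); exact null distribution for small samples without ties,
    normal approximation with tie correction otherwise.  All-zero differences
    give p = 1 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = y - x
    if np.all(d == 0):
        warnings.warn("all paired differences are zero; Wilcoxon p = 1")
        return 1.0
    res = stats.wilcoxon(x, y, zero_method="wilcox", alternative="two-sided", method="auto")
    return float(res.pvalue)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) and two-sided p.

    A constant input vector makes the correlation undefined: returns
    (nan, nan) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("samples must have equal length")
    if len(x) < 3:
        raise ValueError("Spearman correlation needs >= 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: Spearman correlation undefined")
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def bland_altman(x, y) -> BlandAltmanResult:
    """Bias and 95% limits of agreement of the paired differences y - x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if len(x) < 2:
        raise ValueError("Bland-Altman needs >= 2 pairs")
    d = y - x
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(bias, bias - 1.96 * sd, bias + 1.96 * sd, len(d))


def percent_median_difference(scan1, scan2) -> float:
    """Median over subjects of 100 (scan2_i - scan1_i) / scan1_i."""
    s1 = np.asarray(scan1, dtype=float)
    s2 = np.asarray(scan2, dtype=float)
    if s1.shape != s2.shape:
        raise ValueError("paired samples must have equal length")
    if np.any(s1 <= 0):
        raise ValueError("reference (scan 1) values must be positive")
    return float(np.median(100.0 * (s2 - s1) / s1))
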