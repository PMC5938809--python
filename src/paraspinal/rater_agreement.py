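"""Agreement between raters: mask overlap, ICC, and coefficient of variation.

Three complementary views of inter-rater reliability:

* **Area fraction overlap** — pixels foreground in *all* raters' masks
  divided by the cumulative masked area. The denominator is implemented as
  the union of the masks, which keeps the statistic in [0, 1] and matches
  the all-raters/any-rater reading of overlap maps.
* **ICC(A,k)** — intraclass correlation for absolute agreement of the mean
  of k raters, from the two-way crossed ANOVA mean squares, with the
  F-based 95 % confidence interval of McGraw & Wong (1996). The point
  estimate is identical whether the rater factor is treated as random or
  fixed (mixed), so one estimator serves the "2-way mixed, absolute
  agreement, mean of k" specification.
* **Between-rater CV** — sample standard deviation across raters over
  their mean, one value per measured unit.

Interpretation bands follow Cicchetti (1994): < 0.40 poor, 0.40–0.59 fair,
0.60–0.74 good, >= 0.75 excellent (0.75 itself counts as excellent).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import CompletenessError, GridMismatchError
from .image_io import RoiMask

CICCHETTI_BANDS = (
    (0.40, "poor"),
    (0.60, "fair"),
    (0.75, "good"),
    (math.inf, "excellent"),
)


def interpret_icc(estimate: float) -> str:
    """Cicchetti qualitative band for an ICC point estimate."""
    for upper, name in CICCHETTI_BANDS:
        if estimate < upper:
            return name
    return "excellent"


@dataclass(frozen=True)
class OverlapResult:
    """Area fraction overlap of >= 2 rater masks on one grid."""

    fraction: float
    n_common: int
    n_union: int
    n_raters: int
    labels: dict = field(default_factory=dict)
    empty_union: bool = False

    def __post_init__(self):
        if self.n_common > self.n_union:
            raise ValueError("n_common cannot exceed n_union")


@dataclass(frozen=True)
class ICCResult:
    """ICC(A,k) point estimate, 95 % CI, and ANOVA mean squares."""

    estimate: float
    ci_low: float
    ci_high: float
    k: int
    n: int
    interpretation: str
    mean_squares: tuple[float, float, float]  # (MS_rows, MS_cols, MS_error)
    degenerate: bool = False


@dataclass(frozen=True)
class CVRecord:
    """Between-rater coefficient of variation for one measured unit."""

    cv: float
    measure_value: float  # mean across raters
    labels: dict = field(default_factory=dict)
    undefined: bool = False


def area_fraction_overlap(masks: list[RoiMask]) -> OverlapResult:
    """Fraction of the union area covered by every rater's mask.

    All masks must share one grid and one (subject, muscle, side, method)
    label tuple; only the rater varies.
    """
    if len(masks) < 2:
        raise ValueError("need at least 2 masks to compute overlap")
    shape = masks[0].mask.shape
    key = (masks[0].subject_id, masks[0].muscle, masks[0].side, masks[0].method)
    for m in masks[1:]:
        if m.mask.shape != shape:
            raise GridMismatchError(
                f"mask grids differ: {m.mask.shape} vs {shape}"
            )
        if (m.subject_id, m.muscle, m.side, m.method) != key:
            raise ValueError(
                f"masks mix labels: {(m.subject_id, m.muscle, m.side, m.method)} vs {key}"
            )
    common = np.logical_and.reduce([m.mask for m in masks])
    union = np.logical_or.reduce([m.mask for m in masks])
    n_common, n_union = int(common.sum()), int(union.sum())
    empty = n_union == 0
    fraction = 0.0 if empty else n_common / n_union
    labels = {"subject": key[0], "muscle": key[1], "side": key[2], "method": key[3]}
    return OverlapResult(fraction, n_common, n_union, len(masks), labels, empty_union=empty)


def pivot_scores(table: pd.DataFrame) -> np.ndarray:
    """Pivot a long (subject, rater, score) table to a complete n x k grid."""
    wide = table.pivot(index="subject", columns="rater", values="score")
    if wide.isna().any().any():
        missing = int(wide.isna().sum().sum())
        raise CompletenessError(f"score grid has {missing} missing cells")
    return wide.to_numpy(dtype=float)


def _anova_mean_squares(grid: np.ndarray) -> tuple[float, float, float]:
    """Two-way crossed ANOVA mean squares: rows = subjects, cols = raters."""
    n, k = grid.shape
    grand = grid.mean()
    row_means = grid.mean(axis=1)
    col_means = grid.mean(axis=0)
    ms_rows = k * np.sum((row_means - grand) ** 2) / (n - 1)
    ms_cols = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = grid - row_means[:, None] - col_means[None, :] + grand
    ms_error = np.sum(resid**2) / ((n - 1) * (k - 1))
    return float(ms_rows), float(ms_cols), float(ms_error)


def icc_absolute_agreement_k(
    table: pd.DataFrame | np.ndarray, alpha: float = 0.05
) -> ICCResult:
    """ICC(A,k): absolute agreement of the mean of k raters over n subjects.

    Accepts a long (subject, rater, score) table or an n x k array with no
    missing cells. Point estimate
    ``(MS_rows - MS_err) / (MS_rows + (MS_cols - MS_err) / n)``; the CI is
    the F-based interval for the single-rater absolute-agreement
    coefficient stepped up to k raters by the Spearman-Brown relation.
    A grid with no subject variance is flagged degenerate and reported as
    computed (the estimate may be <= 0).
    """
    if isinstance(table, pd.DataFrame):
        grid = pivot_scores(table)
    else:
        grid = np.asarray(table, dtype=float)
        if np.isnan(grid).any():
            raise CompletenessError("score grid has missing cells")
    n, k = grid.shape
    if n < 2 or k < 2:
        raise ValueError(f"need n >= 2 subjects and k >= 2 raters, got {n} x {k}")

    msr, msc, mse = _anova_mean_squares(grid)
    degenerate = msr == 0
    denom = msr + (msc - mse) / n
    estimate = 0.0 if denom == 0 else (msr - mse) / denom
    estimate = min(float(estimate), 1.0)

    ci_low, ci_high = _icc_a_k_ci(msr, msc, mse, n, k, alpha)
    ci_low = min(ci_low, estimate)
    ci_high = max(ci_high, estimate)
    return ICCResult(
        estimate=estimate,
        ci_low=ci_low,
        ci_high=ci_high,
        k=k,
        n=n,
        interpretation=interpret_icc(estimate),
        mean_squares=(msr, msc, mse),
        degenerate=bool(degenerate),
    )


def _icc_a_k_ci(msr: float, msc: float, mse: float, n: int, k: int, alpha: float):
    """McGraw & Wong F-based CI for ICC(A,k).

    Bounds for the single-measure coefficient ICC(A,1) come from an F
    statistic with Satterthwaite degrees of freedom; the average-measure
    bounds follow by the Spearman-Brown step-up k*r / (1 + (k-1) r).
    """
    denom1 = msr + (k - 1) * mse + k * (msc - mse) / n
    icc1 = 0.0 if denom1 == 0 else (msr - mse) / denom1
    icc1 = min(icc1, 1.0 - 1e-15)

    if mse == 0 and msc == msr:  # perfect agreement: interval collapses
        return 1.0, 1.0
    a = k * icc1 / (n * (1 - icc1))
    b = 1 + k * icc1 * (n - 1) / (n * (1 - icc1))
    num = (a * msc + b * mse) ** 2
    den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = num / den if den > 0 else (n - 1) * (k - 1)
    f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lo_den = f1 * (k * msc + (k * n - k - n) * mse) + n * msr
    hi_den = k * msc + (k * n - k - n) * mse + n * f2 * msr
    l1 = n * (msr - f1 * mse) / lo_den if lo_den != 0 else -math.inf
    u1 = n * (f2 * msr - mse) / hi_den if hi_den != 0 else math.inf

    def step_up(r1: float) -> float:
        d = 1 + (k - 1) * r1
        return k * r1 / d if d != 0 else math.inf

    return float(step_up(l1)), float(min(step_up(u1), 1.0))


def between_rater_cv(values, labels: dict | None = None) -> CVRecord:
    """Sample-sd-over-mean coefficient of variation across >= 2 rater values.

    Flagged undefined (cv = nan) when the rater mean is not positive.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError(f"need >= 2 rater values, got {arr.size}")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    if mean <= 0:
        return CVRecord(cv=math.nan, measure_value=mean, labels=dict(labels or {}),
                        undefined=True)
    return CVRecord(cv=sd / mean, measure_value=mean, labels=dict(labels or {}))
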