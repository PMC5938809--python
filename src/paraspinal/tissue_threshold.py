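"""Fat/muscle classification by two-Gaussian histogram decomposition.

For each ROI, the histogram of masked pixel intensities is modelled as the
sum of two scaled Gaussian densities — a dark muscle component and a bright
fat component. The intensity at which the two fitted densities intersect
(between the component means) is the fat/muscle threshold: pixels strictly
above it are fat, pixels at or below are muscle.

The fit is weighted nonlinear least squares against the binned counts, not
expectation-maximization on the raw pixels: the binned model is what the
threshold is defined on, and it is robust to the heavy single-pixel tails
of real ROIs. Thresholds are computed per ROI (per muscle/side/rater/
method) by default; pooling across ROIs of one subject is available but
off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize
from skimage.filters import threshold_otsu

from .exceptions import DegenerateHistogramError, EmptyRoiError, FitError
from .image_io import AxialImage, RoiMask

#: Label values used in TissueLabels.label_map.
LABEL_BACKGROUND, LABEL_MUSCLE, LABEL_FAT = 0, 1, 2

#: Fitted means closer than this multiple of the wider sd trigger the
#: overlap warning (the two components are not meaningfully separated).
OVERLAP_SD_FACTOR = 0.5

#: With overlapping components, a high-mean component carrying less than
#: this mass fraction is treated as absent (no-fat ROI; FSF reported as 0).
MIN_HI_MASS_FRACTION = 0.01


@dataclass(frozen=True)
class IntensityHistogram:
    """Equal-width histogram of one ROI's pixel intensities."""

    bin_edges: np.ndarray  # length B + 1, strictly increasing
    counts: np.ndarray  # length B, non-negative integers
    n_pixels: int

    def __post_init__(self):
        edges = np.asarray(self.bin_edges, dtype=float)
        counts = np.asarray(self.counts)
        if len(edges) != len(counts) + 1:
            raise ValueError("bin_edges must be one longer than counts")
        if len(counts) < 8:
            raise ValueError(f"need >= 8 bins, got {len(counts)}")
        if not np.all(np.diff(edges) > 0):
            raise ValueError("bin_edges must be strictly increasing")
        if counts.sum() != self.n_pixels:
            raise ValueError("sum(counts) must equal n_pixels")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


@dataclass(frozen=True)
class GaussianPair:
    """Two fitted Gaussian components (lo = muscle, hi = fat) and their threshold.

    Weights are pixel masses (the component's share of ``n_pixels``).
    ``fallback_midpoint`` marks a threshold taken as the mean midpoint
    because no density intersection lay between the means;
    ``overlap_warning`` marks components too close to be meaningfully
    distinct.
    """

    weight_lo: float
    mean_lo: float
    sd_lo: float
    weight_hi: float
    mean_hi: float
    sd_hi: float
    threshold: float = math.nan
    converged: bool = False
    rss: float = 0.0
    overlap_warning: bool = False
    fallback_midpoint: bool = False

    def __post_init__(self):
        if self.mean_hi <= self.mean_lo:
            raise ValueError("mean_hi must exceed mean_lo")
        if self.sd_lo <= 0 or self.sd_hi <= 0:
            raise ValueError("component sds must be positive")
        if self.weight_lo <= 0 or self.weight_hi <= 0:
            raise ValueError("component weights must be positive")


@dataclass(frozen=True)
class TissueLabels:
    """Per-pixel fat/muscle labels inside one ROI."""

    label_map: np.ndarray  # {0 background, 1 muscle, 2 fat}
    n_fat: int
    n_muscle: int
    threshold_used: float
    no_fat_flag: bool = False  # set when an overlapping fit was read as "no fat"


def build_histogram(image: AxialImage, mask: RoiMask, n_bins: int = 64) -> IntensityHistogram:
    """Histogram the masked intensities into equal-width bins over [min, max].

    The right-most bin is closed, all others half-open, so every masked
    pixel is counted exactly once.
    """
    mask.check_grid(image)
    if n_bins < 8:
        raise ValueError(f"n_bins must be >= 8, got {n_bins}")
    values = image.intensities[mask.mask]
    if values.size == 0:
        raise EmptyRoiError("mask has no foreground pixels")
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        raise DegenerateHistogramError(
            f"all {values.size} masked pixels share intensity {lo}; no histogram"
        )
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    return IntensityHistogram(edges, counts, int(values.size))


def _model(x: np.ndarray, w1: float, m1: float, s1: float, w2: float, m2: float, s2: float,
           bin_width: float) -> np.ndarray:
    """Expected bin counts: pixel-mass-weighted Gaussian densities times bin width."""
    g1 = w1 / (s1 * math.sqrt(2 * math.pi)) * np.exp(-0.5 * ((x - m1) / s1) ** 2)
    g2 = w2 / (s2 * math.sqrt(2 * math.pi)) * np.exp(-0.5 * ((x - m2) / s2) ** 2)
    return bin_width * (g1 + g2)


def _moments_split(values_centers, counts, split):
    """Mass/mean/sd of histogram mass on each side of a split point."""
    lo_side = values_centers <= split
    out = []
    for sel in (lo_side, ~lo_side):
        c = counts[sel].astype(float)
        x = values_centers[sel]
        mass = c.sum()
        if mass < 1:
            out.append(None)
            continue
        mean = float((c * x).sum() / mass)
        var = float((c * (x - mean) ** 2).sum() / mass)
        out.append((float(mass), mean, math.sqrt(max(var, 1e-12))))
    return out


def _initializations(hist: IntensityHistogram):
    """Otsu-split moments first; quantile (25th/75th percentile) split second."""
    centers = hist.bin_centers
    counts = hist.counts
    inits = []
    try:
        otsu = threshold_otsu(hist=(counts.astype(float), centers))
        sides = _moments_split(centers, counts, otsu)
        if sides[0] is not None and sides[1] is not None:
            inits.append(sides)
    except Exception:
        pass
    # quantile-based fallback: means at the 25th and 75th weighted percentiles
    cum = np.cumsum(counts) / counts.sum()
    q25 = centers[np.searchsorted(cum, 0.25)]
    q75 = centers[min(np.searchsorted(cum, 0.75), len(centers) - 1)]
    split = 0.5 * (q25 + q75)
    sides = _moments_split(centers, counts, split)
    if sides[0] is not None and sides[1] is not None:
        span = (hist.bin_edges[-1] - hist.bin_edges[0]) / 6
        n = counts.sum()
        inits.append([(n / 2, float(q25), span), (n / 2, float(q75), span)])
        if sides not in inits:
            inits.append(sides)
    return inits


def fit_two_gaussian(hist: IntensityHistogram) -> GaussianPair:
    """Fit the two-component scaled-Gaussian model to the binned counts.

    Nonlinear least squares at the bin centers; components are sorted so
    the high-mean (fat) component comes second. If the fitted means are
    closer than half the wider sd, the pair carries an overlap warning
    rather than failing: single-tissue ROIs are a legitimate input.
    """
    centers = hist.bin_centers
    counts = hist.counts.astype(float)
    width = hist.bin_width
    span = hist.bin_edges[-1] - hist.bin_edges[0]
    n = float(hist.n_pixels)

    lower = [1e-6, hist.bin_edges[0] - span, width / 10, 1e-6, hist.bin_edges[0] - span, width / 10]
    upper = [2 * n, hist.bin_edges[-1] + span, 2 * span, 2 * n, hist.bin_edges[-1] + span, 2 * span]

    diagnostics = {}
    best = None
    for i, init in enumerate(_initializations(hist)):
        (w1, m1, s1), (w2, m2, s2) = init
        p0 = np.clip([w1, m1, s1, w2, m2, s2], lower, upper)
        try:
            popt, _ = optimize.curve_fit(
                lambda x, *p: _model(x, *p, bin_width=width),
                centers,
                counts,
                p0=p0,
                bounds=(lower, upper),
                maxfev=20000,
            )
            rss = float(np.sum((counts - _model(centers, *popt, bin_width=width)) ** 2))
            if best is None or rss < best[1]:
                best = (popt, rss)
        except (RuntimeError, ValueError) as exc:
            diagnostics[f"init_{i}"] = str(exc)
    if best is None:
        raise FitError("two-Gaussian fit failed from every initialization", diagnostics)

    popt, rss = best
    comp = sorted([(popt[0], popt[1], popt[2]), (popt[3], popt[4], popt[5])], key=lambda c: c[1])
    (w_lo, m_lo, s_lo), (w_hi, m_hi, s_hi) = comp
    if m_hi <= m_lo:  # identical means: nudge so the pair stays constructible
        m_hi = m_lo + 1e-9 * max(1.0, abs(m_lo))
    overlap = (m_hi - m_lo) < OVERLAP_SD_FACTOR * max(s_lo, s_hi)
    pair = GaussianPair(
        weight_lo=float(w_lo), mean_lo=float(m_lo), sd_lo=float(s_lo),
        weight_hi=float(w_hi), mean_hi=float(m_hi), sd_hi=float(s_hi),
        converged=True, rss=rss, overlap_warning=bool(overlap),
    )
    threshold, fallback = find_intersection(pair, return_fallback=True)
    return replace(pair, threshold=threshold, fallback_midpoint=fallback)


def find_intersection(pair: GaussianPair, return_fallback: bool = False):
    """The intensity where the two weighted component densities are equal.

    Solved in closed form from the quadratic obtained by equating the
    log-densities. Only a root strictly between the means is a valid
    threshold; if none exists (extreme weight imbalance), the midpoint of
    the means is returned with the fallback flag set.
    """
    m1, s1, w1 = pair.mean_lo, pair.sd_lo, pair.weight_lo
    m2, s2, w2 = pair.mean_hi, pair.sd_hi, pair.weight_hi
    if m1 == m2:
        raise ValueError("component means are equal; no intersection exists")

    # log w1*phi1(x) = log w2*phi2(x)  =>  a x^2 + b x + c = 0
    a = 0.5 / s2**2 - 0.5 / s1**2
    b = m1 / s1**2 - m2 / s2**2
    c = (
        0.5 * m2**2 / s2**2
        - 0.5 * m1**2 / s1**2
        + math.log((w1 * s2) / (w2 * s1))
    )
    roots = []
    if abs(a) < 1e-300 or s1 == s2:
        # equal variances: the log-density difference is linear
        a_lin = m1 / s1**2 - m2 / s2**2
        c_lin = 0.5 * m2**2 / s2**2 - 0.5 * m1**2 / s1**2 + math.log((w1 * s2) / (w2 * s1))
        if a_lin != 0:
            roots = [-c_lin / a_lin]
    else:
        disc = b * b - 4 * a * c
        if disc >= 0:
            sq = math.sqrt(disc)
            roots = [(-b - sq) / (2 * a), (-b + sq) / (2 * a)]
    between = [r for r in roots if m1 < r < m2]
    if between:
        # with two in-between roots (rare), take the one closest to midpoint
        mid = 0.5 * (m1 + m2)
        t = min(between, key=lambda r: abs(r - mid))
        return (float(t), False) if return_fallback else float(t)
    t = 0.5 * (m1 + m2)
    return (float(t), True) if return_fallback else float(t)


def classify_pixels(image: AxialImage, mask: RoiMask, threshold: float) -> TissueLabels:
    """Label masked pixels: strictly above the threshold fat, otherwise muscle."""
    mask.check_grid(image)
    if not mask.mask.any():
        raise EmptyRoiError("mask has no foreground pixels")
    label_map = np.zeros(image.shape, dtype=np.uint8)
    fg = mask.mask
    fat = fg & (image.intensities > threshold)
    label_map[fg] = LABEL_MUSCLE
    label_map[fat] = LABEL_FAT
    n_fat = int(fat.sum())
    return TissueLabels(
        label_map=label_map,
        n_fat=n_fat,
        n_muscle=int(fg.sum()) - n_fat,
        threshold_used=float(threshold),
    )


def segment_roi(image: AxialImage, mask: RoiMask, n_bins: int = 64) -> tuple[GaussianPair, TissueLabels]:
    """Full per-ROI pipeline: histogram, two-Gaussian fit, threshold, classify.

    A fit whose components overlap (warning set) and whose bright component
    carries under 1 % of the pixel mass is read as a single-tissue,
    fat-free ROI: every pixel is labelled muscle and the no-fat flag set.
    """
    hist = build_histogram(image, mask, n_bins=n_bins)
    pair = fit_two_gaussian(hist)
    hi_mass_frac = pair.weight_hi / (pair.weight_lo + pair.weight_hi)
    if pair.overlap_warning and hi_mass_frac < MIN_HI_MASS_FRACTION:
        labels = classify_pixels(image, mask, threshold=float(image.intensities[mask.mask].max()))
        labels = replace(labels, no_fat_flag=True)
        return pair, labels
    return pair, classify_pixels(image, mask, pair.threshold)


def pooled_histogram(image: AxialImage, masks: list[RoiMask], n_bins: int = 64) -> IntensityHistogram:
    """Histogram pooled over several ROIs of one subject (off-by-default option)."""
    union = np.zeros(image.shape, dtype=bool)
    for m in masks:
        m.check_grid(image)
        union |= m.mask
    pooled = RoiMask(union, muscle=masks[0].muscle, side=masks[0].side,
                     rater_id=masks[0].rater_id, method=masks[0].method,
                     subject_id=masks[0].subject_id)
    return build_histogram(image, pooled, n_bins=n_bins)
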