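"""Thresholding, binary morphology and moment-based object labeling.

Three binarisation strategies used across the fluorescence analyses:

* :func:`otsu_threshold` — global threshold maximising between-class
  intensity variance; used for nuclear (DAPI) segmentation.
* :func:`max_entropy_threshold` — the Kapur–Sahoo–Wong criterion: the
  threshold maximising the summed Shannon entropies of the background and
  foreground sub-histograms; used for live/dead area segmentation.
* :func:`adaptive_threshold` — local-mean threshold with a sensitivity
  factor; used for cytoskeleton (phalloidin) segmentation.

Both global thresholds operate on one-bin-per-level integer histograms
(256 or 65536 bins; 16-bit data is not rebinned) and return the largest
level *t* of the background class, i.e. foreground is strictly ``> t``.
Ties in the objective are broken toward the smallest level.

Connected components are 8-connected throughout.  Equivalent-ellipse
semi-axes come from the eigenvalues λ₁ ≥ λ₂ of the pixel-coordinate
covariance as a = 2√λ₁, b = 2√λ₂, and eccentricity is
E = √(1 − b²/a²) — the standard image-moment definition, 0 for a circle
and approaching 1 for spindle-like shapes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import diamond

from .image_io import PixelGrid

__all__ = [
    "DegenerateHistogramError",
    "IntensityHistogram",
    "BinaryMask",
    "LabeledObject",
    "intensity_histogram",
    "otsu_threshold",
    "max_entropy_threshold",
    "adaptive_threshold",
    "threshold_mask",
    "morphological_open",
    "fill_holes",
    "remove_small",
    "label_objects",
    "default_window",
]

#: 8-connectivity structuring element used for all component labeling.
_CONN8 = np.ones((3, 3), dtype=bool)


class DegenerateHistogramError(ValueError):
    """Raised when a histogram has fewer than two occupied levels."""


@dataclass(frozen=True)
class IntensityHistogram:
    """Occurrences per integer intensity level (length ``2**bit_depth``)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.ndim != 1 or c.size < 2:
            raise ValueError("counts must be a 1D array with >= 2 levels")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        if c.sum() == 0:
            raise ValueError("histogram of an empty image")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_occupied(self) -> int:
        return int((self.counts > 0).sum())


def intensity_histogram(grid: PixelGrid) -> IntensityHistogram:
    """One-bin-per-level histogram of a grid (256 or 65536 bins)."""
    counts = np.bincount(grid.values.ravel(), minlength=2**grid.bit_depth)
    return IntensityHistogram(counts)


def _as_counts(hist: IntensityHistogram | np.ndarray) -> np.ndarray:
    if isinstance(hist, IntensityHistogram):
        return hist.counts
    return IntensityHistogram(np.asarray(hist)).counts


def otsu_threshold(hist: IntensityHistogram | np.ndarray) -> int:
    """Level t maximising between-class variance of {<= t} vs {> t}.

    Raises :class:`DegenerateHistogramError` when only one level is
    occupied (no separable classes).  Ties break to the smallest level.
    """
    counts = _as_counts(hist)
    total = counts.sum()
    if (counts > 0).sum() < 2:
        raise DegenerateHistogramError("single occupied level; no separable classes")
    p = counts / total
    levels = np.arange(counts.size)
    w0 = np.cumsum(p)
    mu0 = np.cumsum(p * levels)
    mu_t = mu0[-1]
    csum = np.cumsum(counts)
    valid = (csum > 0) & (csum < total)
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * w0 - mu0) ** 2 / (w0 * (1.0 - w0))
    sigma_b[~valid] = -np.inf
    return int(np.argmax(sigma_b))


def max_entropy_threshold(hist: IntensityHistogram | np.ndarray) -> int:
    """Level t maximising summed Shannon entropies of the two classes.

    The objective is H0(t) + H1(t) with H0 the entropy of the normalised
    sub-histogram over levels <= t and H1 over levels > t; zero-count
    levels contribute nothing.  Candidates are restricted to splits where
    both classes are occupied; ties break to the smallest level.
    """
    counts = _as_counts(hist)
    total = counts.sum()
    if (counts > 0).sum() < 2:
        raise DegenerateHistogramError("single occupied level; no separable classes")
    p = counts / total
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    s = np.cumsum(-plogp)  # -sum p log p over levels <= t
    s_total = s[-1]
    p0 = np.cumsum(p)
    p1 = 1.0 - p0
    csum = np.cumsum(counts)
    valid = (csum > 0) & (csum < total)
    with np.errstate(divide="ignore", invalid="ignore"):
        h0 = s / p0 + np.log(p0)
        h1 = (s_total - s) / p1 + np.log(p1)
    obj = h0 + h1
    obj[~valid] = -np.inf
    return int(np.argmax(obj))


@dataclass(frozen=True)
class BinaryMask:
    """2D boolean grid with the pixel size of the grid it came from."""

    values: np.ndarray
    pd: float = 1.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=bool)
        if v.ndim != 2:
            raise ValueError("mask must be 2D")
        if not (self.pd > 0):
            raise ValueError(f"pixel size pd must be > 0, got {self.pd}")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def foreground_count(self) -> int:
        return int(self.values.sum())


def threshold_mask(grid: PixelGrid, level: int) -> BinaryMask:
    """Foreground = pixels strictly greater than ``level``."""
    return BinaryMask(grid.values > level, pd=grid.pd)


def default_window(shape: tuple[int, int]) -> int:
    """Default adaptive window: 1/8 of the shorter side, rounded up to odd."""
    w = int(np.ceil(min(shape) / 8))
    w = max(w, 3)
    if w % 2 == 0:
        w += 1
    return w


def adaptive_threshold(
    grid: PixelGrid,
    window: int | None = None,
    sensitivity: float = 0.9,
) -> BinaryMask:
    """Local-mean threshold: foreground iff value > local_mean × (2 − s).

    ``sensitivity`` s ∈ [0, 1] scales the acceptance factor: s = 1 is the
    most lenient (factor 1), s = 0 the strictest (factor 2), so foreground
    grows monotonically with s.  The local mean is computed over a square
    ``window`` (odd, >= 3; default 1/8 of the shorter side) with replicate
    padding at the borders.
    """
    if window is None:
        window = default_window(grid.shape)
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    if not (0.0 <= sensitivity <= 1.0):
        raise ValueError(f"sensitivity must be in [0, 1], got {sensitivity}")
    local_mean = ndimage.uniform_filter(
        grid.values.astype(np.float64), size=window, mode="nearest"
    )
    fg = grid.values > local_mean * (2.0 - sensitivity)
    return BinaryMask(fg, pd=grid.pd)


def morphological_open(mask: BinaryMask, radius: int = 3) -> BinaryMask:
    """Opening (erosion then dilation) with a diamond (L1-ball) element."""
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")
    se = diamond(radius).astype(bool)
    opened = ndimage.binary_opening(mask.values, structure=se)
    return BinaryMask(opened, pd=mask.pd)


def fill_holes(mask: BinaryMask) -> BinaryMask:
    """Turn background components not connected to the border into foreground."""
    return BinaryMask(ndimage.binary_fill_holes(mask.values), pd=mask.pd)


def remove_small(mask: BinaryMask, min_area: int) -> BinaryMask:
    """Delete 8-connected components with area strictly below ``min_area``."""
    if min_area < 0:
        raise ValueError(f"min_area must be >= 0, got {min_area}")
    if min_area <= 1:
        return mask
    labels, n = ndimage.label(mask.values, structure=_CONN8)
    if n == 0:
        return mask
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_area
    keep[0] = False
    return BinaryMask(keep[labels], pd=mask.pd)


@dataclass(frozen=True, eq=False)
class LabeledObject:
    """One 8-connected foreground component with shape descriptors.

    ``a`` and ``b`` are the semi-axes (px) of the equivalent ellipse from
    second-order moments; ``eccentricity`` is √(1 − b²/a²).  Single-pixel
    objects have a = b = eccentricity = 0.  Note that a one-pixel-wide
    line has b = 0 and therefore eccentricity exactly 1.
    """

    label: int
    pixels: np.ndarray  # (k, 2) array of (row, col)
    area_px: int
    centroid: tuple[float, float]
    a: float
    b: float
    eccentricity: float


def _ellipse_axes(rows: np.ndarray, cols: np.ndarray) -> tuple[float, float, float]:
    if rows.size < 2:
        return 0.0, 0.0, 0.0
    coords = np.vstack([rows, cols]).astype(np.float64)
    cov = np.cov(coords, ddof=0)
    evals = np.linalg.eigvalsh(cov)  # ascending
    lam2 = max(float(evals[0]), 0.0)
    lam1 = max(float(evals[1]), 0.0)
    a = 2.0 * np.sqrt(lam1)
    b = 2.0 * np.sqrt(lam2)
    if a <= 0:
        return 0.0, 0.0, 0.0
    ecc = float(np.sqrt(max(0.0, 1.0 - (b * b) / (a * a))))
    return a, b, ecc


def label_objects(mask: BinaryMask) -> list[LabeledObject]:
    """Label 8-connected components and compute moment descriptors."""
    labels, n = ndimage.label(mask.values, structure=_CONN8)
    objects: list[LabeledObject] = []
    for i, sl in zip(range(1, n + 1), ndimage.find_objects(labels)):
        sub = labels[sl] == i
        rr, cc = np.nonzero(sub)
        rr = rr + sl[0].start
        cc = cc + sl[1].start
        a, b, ecc = _ellipse_axes(rr, cc)
        objects.append(
            LabeledObject(
                label=i,
                pixels=np.column_stack([rr, cc]),
                area_px=int(rr.size),
                centroid=(float(rr.mean()), float(cc.mean())),
                a=a,
                b=b,
                eccentricity=ecc,
            )
        )
    return objects
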