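"""Scaffold-image analyses: viability areas, spatial distribution, morphology.

Three read-outs computed from fluorescence images of cells embedded in a
3D hydrogel scaffold, cultured with or without perfusion:

1. **Live/dead viability areas** — each channel of a calcein/ethidium
   pair is segmented with the maximum-entropy threshold, and the covered
   physical area is A = np · pd² with *np* the foreground pixel count and
   *pd* the pixel edge length in µm.
2. **Nuclei spatial distribution** — the nuclear channel is segmented
   with Otsu's threshold, cleaned by a morphological opening with a
   diamond element, and the resulting objects are counted per scaffold
   region (edge vs. core) or binned into a radial profile.
3. **Eccentricity morphometry** — the cytoskeleton channel is binarised
   with a high-sensitivity adaptive threshold, small objects are removed,
   holes are filled, and the per-cell eccentricity distribution is
   summarised by its skewness and the fraction of highly eccentric
   (E > 0.8) cells.

The nonparametric tests used to compare conditions (Mann–Whitney,
Kruskal–Wallis, two-sample Kolmogorov–Smirnov) are re-exported from
:mod:`perfquant.stats`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .image_io import PixelGrid
from .segmentation import (
    BinaryMask,
    DegenerateHistogramError,
    LabeledObject,
    adaptive_threshold,
    fill_holes,
    intensity_histogram,
    label_objects,
    max_entropy_threshold,
    morphological_open,
    otsu_threshold,
    remove_small,
    threshold_mask,
)
from .stats import (  # noqa: F401  (re-exported module surface)
    DegenerateSampleError,
    TestResult,
    kruskal_wallis,
    ks_two_sample,
    mann_whitney,
    skewness,
)

__all__ = [
    "AreaQuantification",
    "RegionCount",
    "RadialProfile",
    "EccentricityDistribution",
    "EmptyDistributionError",
    "quantify_area",
    "viability_areas",
    "area_fold_change",
    "count_nuclei",
    "radial_profile",
    "edge_core_summary",
    "split_edge_core",
    "eccentricity_pipeline",
    "mann_whitney",
    "kruskal_wallis",
    "ks_two_sample",
    "skewness",
    "TestResult",
]


class EmptyDistributionError(ValueError):
    """Raised when a pipeline leaves no objects to summarise."""


@dataclass(frozen=True)
class AreaQuantification:
    """Physical area covered by segmented signal: A = np · pd²."""

    np_count: int
    pd: float
    A: float

    @classmethod
    def from_mask(cls, mask: BinaryMask) -> "AreaQuantification":
        np_count = mask.foreground_count
        return cls(np_count=np_count, pd=mask.pd, A=np_count * mask.pd**2)


@dataclass(frozen=True)
class RegionCount:
    """Cell count for one image of one scaffold region."""

    region: str
    image_id: str
    cell_count: int

    def __post_init__(self) -> None:
        if self.cell_count < 0:
            raise ValueError("cell_count must be >= 0")


@dataclass(frozen=True)
class RadialProfile:
    """Object counts per annulus around the scaffold centre."""

    center: tuple[float, float]
    bin_edges: np.ndarray
    counts: np.ndarray
    n_excluded: int

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=np.float64)
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.size != edges.size - 1:
            raise ValueError("len(counts) must equal len(bin_edges) - 1")
        if not np.all(np.diff(edges) > 0):
            raise ValueError("bin_edges must be strictly increasing")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts)


@dataclass(frozen=True)
class EccentricityDistribution:
    """Per-cell eccentricities with skewness and high-E fraction."""

    values: np.ndarray
    skewness: float
    frac_high: float
    cutoff: float = 0.8


def quantify_area(mask: BinaryMask) -> AreaQuantification:
    """Physical area of the mask foreground: A = np · pd²."""
    return AreaQuantification.from_mask(mask)


def viability_areas(
    live: PixelGrid, dead: PixelGrid
) -> tuple[AreaQuantification, AreaQuantification]:
    """Maximum-entropy segmentation and area quantification per channel."""
    if live.shape != dead.shape or live.pd != dead.pd:
        raise ValueError("live and dead channels must share shape and pixel size")
    out = []
    for name, grid in (("live", live), ("dead", dead)):
        try:
            t = max_entropy_threshold(intensity_histogram(grid))
        except DegenerateHistogramError as err:
            raise DegenerateHistogramError(f"channel '{name}': {err}") from err
        out.append(quantify_area(threshold_mask(grid, t)))
    return out[0], out[1]


def area_fold_change(
    cond_a: Sequence[float], cond_b: Sequence[float]
) -> tuple[float, TestResult]:
    """mean(b)/mean(a) fold change plus a Mann–Whitney comparison."""
    a = np.asarray(cond_a, dtype=np.float64).ravel()
    b = np.asarray(cond_b, dtype=np.float64).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both conditions need >= 1 area")
    if a.mean() == 0:
        raise ZeroDivisionError("mean of the reference condition is zero")
    return float(b.mean() / a.mean()), mann_whitney(a, b)


def count_nuclei(nuclei: PixelGrid, opening_radius: int = 3) -> list[LabeledObject]:
    """Otsu threshold -> diamond opening -> labeled nuclei objects."""
    t = otsu_threshold(intensity_histogram(nuclei))
    mask = morphological_open(threshold_mask(nuclei, t), radius=opening_radius)
    return label_objects(mask)


def radial_profile(
    objects: Sequence[LabeledObject],
    center: tuple[float, float],
    n_bins: int,
    max_r: float,
) -> RadialProfile:
    """Bin object centroids into equal-width annuli around ``center``.

    Centroids beyond ``max_r`` are excluded and reported in
    ``n_excluded``.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if not (max_r > 0):
        raise ValueError("max_r must be > 0")
    if objects:
        cent = np.array([o.centroid for o in objects], dtype=np.float64)
        d = np.hypot(cent[:, 0] - center[0], cent[:, 1] - center[1])
    else:
        d = np.empty(0)
    edges = np.linspace(0.0, max_r, n_bins + 1)
    inside = d <= max_r
    counts, _ = np.histogram(d[inside], bins=edges)
    return RadialProfile(
        center=center,
        bin_edges=edges,
        counts=counts,
        n_excluded=int((~inside).sum()),
    )


def split_edge_core(
    objects: Sequence[LabeledObject],
    center: tuple[float, float] | None = None,
    core_fraction: float = 0.5,
) -> dict[str, list[LabeledObject]]:
    """Assign objects to ``core``/``edge`` by relative boundary distance.

    The scaffold boundary is estimated as the convex hull of all object
    centroids and the centre as the hull's centroid (a user-supplied
    ``center`` overrides it).  An object is ``core`` when its distance
    from the centre is below ``core_fraction`` of the boundary distance
    along its own direction, else ``edge``.  With fewer than 3 objects
    everything is ``core``.
    """
    if not (0.0 < core_fraction < 1.0):
        raise ValueError("core_fraction must be in (0, 1)")
    out: dict[str, list[LabeledObject]] = {"core": [], "edge": []}
    if len(objects) < 3:
        out["core"] = list(objects)
        return out
    from shapely.geometry import LineString, MultiPoint, Point

    pts = np.array([o.centroid for o in objects], dtype=np.float64)
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    if center is None:
        c = hull.centroid
        center = (c.x, c.y)
    c = np.asarray(center, dtype=np.float64)
    span = float(np.max(np.hypot(pts[:, 0] - c[0], pts[:, 1] - c[1]))) * 4 + 1.0
    for obj, p in zip(objects, pts):
        d = float(np.hypot(*(p - c)))
        if d == 0.0:
            out["core"].append(obj)
            continue
        u = (p - c) / d
        ray = LineString([tuple(c), tuple(c + u * span)])
        inter = ray.intersection(hull.exterior)
        if inter.is_empty:
            boundary_d = d  # centroid on/outside hull edge cases
        else:
            boundary_d = max(
                Point(tuple(c)).distance(g)
                for g in (inter.geoms if hasattr(inter, "geoms") else [inter])
            )
        out["core" if d < core_fraction * boundary_d else "edge"].append(obj)
    return out


def edge_core_summary(
    groups: Mapping[str, Sequence[float]],
) -> tuple[float, TestResult]:
    """Percent edge-vs-core difference of mean counts plus Kruskal–Wallis.

    percent = 100 · (mean_edge − mean_core) / mean_edge, anchored to the
    edge mean (the larger group in a diffusion-limited scaffold).  The
    Kruskal–Wallis test runs across all supplied regions.
    """
    if "edge" not in groups or "core" not in groups:
        raise KeyError("groups must contain 'edge' and 'core'")
    if any(len(v) < 1 for v in groups.values()):
        raise ValueError("every region needs >= 1 image count")
    mean_edge = float(np.mean(groups["edge"]))
    mean_core = float(np.mean(groups["core"]))
    if mean_edge == 0:
        raise ZeroDivisionError("edge mean is zero; percent difference undefined")
    percent = 100.0 * (mean_edge - mean_core) / mean_edge
    test = kruskal_wallis([np.asarray(v, dtype=float) for v in groups.values()])
    return percent, test


def eccentricity_pipeline(
    cyto: PixelGrid,
    window: int | None = None,
    sensitivity: float = 0.9,
    min_area: int = 50,
    frac_high_cutoff: float = 0.8,
) -> EccentricityDistribution:
    """Adaptive threshold -> remove small -> fill holes -> eccentricities.

    Defaults follow the cytoskeleton morphometry recipe: sensitivity 0.9,
    objects under 50 px discarded.  Raises
    :class:`EmptyDistributionError` when nothing survives.
    """
    mask = adaptive_threshold(cyto, window=window, sensitivity=sensitivity)
    mask = remove_small(mask, min_area=min_area)
    mask = fill_holes(mask)
    objects = label_objects(mask)
    if not objects:
        raise EmptyDistributionError("no objects survive the morphology pipeline")
    values = np.array([o.eccentricity for o in objects], dtype=np.float64)
    if values.size >= 3 and np.unique(values).size > 1:
        skew = skewness(values)
    else:
        skew = float("nan")
    return EccentricityDistribution(
        values=values,
        skewness=skew,
        frac_high=float(np.mean(values > frac_high_cutoff)),
        cutoff=frac_high_cutoff,
    )
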