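"""Ground-truthed synthetic scenes for every analysis stage.

No microscope data ships with this package, so each pipeline is
validated against synthetic inputs whose ground truth is known exactly:

* :func:`gen_nuclei_scene` — DAPI-like Gaussian blobs in a circular
  scaffold cross-section with a controllable edge-to-core density
  gradient and signal-to-noise ratio.
* :func:`gen_livedead_scene` — a two-channel live/dead scene of
  sharp-edged disks, each cell assigned to one channel by a Bernoulli
  draw.
* :func:`gen_shape_scene` — filled rotated ellipses with a controllable
  eccentricity distribution (cytoskeleton-like bodies).
* :func:`gen_wound_series` / :func:`render_wound_frame` — exponential
  wound-closure series with multiplicative noise, optionally rendered as
  textured monolayer frames with a smooth central stripe.
* :func:`gen_ct_table` — qPCR Ct tables with known fold changes.

Every generator is bit-reproducible under a fixed seed and returns its
ground truth alongside the rendered data; analyses are tested only
through these declared oracles.  Defaults: 1024×1024 px, 8-bit,
pd = 1.0 µm/px.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pandas_
from scipy.ndimage import gaussian_filter
from scipy.stats import beta as beta_dist
from skimage.draw import disk as draw_disk, ellipse as draw_ellipse

from .image_io import MultiChannelImage, PixelGrid, save_image, write_table
from .wound_kinetics import WoundSeries, normalize_series

__all__ = [
    "PlacementError",
    "SyntheticScene",
    "KineticsGroundTruth",
    "gen_nuclei_scene",
    "gen_livedead_scene",
    "gen_shape_scene",
    "gen_wound_series",
    "render_wound_frame",
    "gen_ct_table",
    "stratified_beta",
    "write_scene",
    "DEFAULT_SHAPE",
]

DEFAULT_SHAPE: tuple[int, int] = (1024, 1024)


class PlacementError(RuntimeError):
    """Raised when objects cannot be placed within the retry budget."""


@dataclass(frozen=True)
class SyntheticScene:
    """Rendered channels plus the ground truth that generated them."""

    channels: MultiChannelImage
    truth: pandas_.DataFrame
    seed: int
    params: dict = field(default_factory=dict)

    @property
    def n_objects(self) -> int:
        return len(self.truth)


@dataclass(frozen=True)
class KineticsGroundTruth:
    """Parameters of one synthetic wound-closure series."""

    tau_true: float
    y0_true: float = 100.0
    noise_sigma: float = 0.0
    times: tuple[float, ...] = (0.0, 2.0, 4.0, 6.0, 8.0, 24.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.tau_true < 0):
            raise ValueError("tau_true must be negative (closing wound)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Independent substreams derived from one top-level seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _quantize(img: np.ndarray, bit_depth: int = 8) -> np.ndarray:
    vmax = 2**bit_depth - 1
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    return np.clip(np.round(img), 0, vmax).astype(dtype)


def _add_blob(canvas: np.ndarray, r: float, c: float, sigma: float, amp: float) -> None:
    h, w = canvas.shape
    e = int(np.ceil(4 * sigma))
    r0, r1 = max(int(r) - e, 0), min(int(r) + e + 1, h)
    c0, c1 = max(int(c) - e, 0), min(int(c) + e + 1, w)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    canvas[r0:r1, c0:c1] += amp * np.exp(
        -((yy - r) ** 2 + (xx - c) ** 2) / (2.0 * sigma * sigma)
    )


def _place_blobs(
    rng: np.random.Generator,
    n: int,
    sample_position: Callable[[np.random.Generator], tuple[float, float]],
    sigma_range: tuple[float, float],
    overlap_tol: float,
    max_tries: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample blob centres with bounded pairwise overlap.

    Two blobs of footprint radii 2σ_i, 2σ_j are accepted when their
    centre distance exceeds (1 − overlap_tol)·2·(σ_i + σ_j).
    """
    centers = np.empty((n, 2))
    sigmas = np.empty(n)
    placed = 0
    tries = 0
    while placed < n:
        if tries >= max_tries:
            raise PlacementError(
                f"placed only {placed}/{n} objects within {max_tries} tries"
            )
        tries += 1
        sigma = rng.uniform(*sigma_range)
        r, c = sample_position(rng)
        if placed:
            d2 = (centers[:placed, 0] - r) ** 2 + (centers[:placed, 1] - c) ** 2
            min_sep = (1.0 - overlap_tol) * 2.0 * (sigmas[:placed] + sigma)
            if np.any(d2 < min_sep**2):
                continue
        centers[placed] = (r, c)
        sigmas[placed] = sigma
        placed += 1
    return centers, sigmas


def gen_nuclei_scene(
    n: int,
    gradient: float = 1.0,
    shape: tuple[int, int] = DEFAULT_SHAPE,
    snr: float = 10.0,
    seed: int = 0,
    sigma_range: tuple[float, float] = (3.0, 6.0),
    amplitude: float = 180.0,
    background: float = 20.0,
    overlap_tol: float = 0.1,
    pd: float = 1.0,
) -> SyntheticScene:
    """DAPI-like nuclei in a circular scaffold section.

    Nuclei are Gaussian blobs (σ in ``sigma_range``) at rejection-sampled
    positions inside the inscribed disk; the radial *density* rises
    linearly from the centre to ``gradient`` times the central density at
    the rim (``gradient`` = 1 is uniform).  ``snr`` is blob amplitude
    over background noise standard deviation.  Ground truth stores exact
    centres and the disk geometry.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if not (snr > 0):
        raise ValueError("snr must be > 0")
    if gradient <= 0:
        raise ValueError("gradient must be > 0")
    place_rng, noise_rng = _rngs(seed, 2)
    h, w = shape
    center = ((h - 1) / 2.0, (w - 1) / 2.0)
    radius = 0.48 * min(shape)
    dens_max = max(1.0, gradient)

    def sample_position(rng: np.random.Generator) -> tuple[float, float]:
        while True:
            rr = radius * np.sqrt(rng.random())
            dens = 1.0 + (gradient - 1.0) * rr / radius
            if rng.random() * dens_max > dens:
                continue
            theta = rng.uniform(0, 2 * np.pi)
            return center[0] + rr * np.sin(theta), center[1] + rr * np.cos(theta)

    centers, sigmas = _place_blobs(
        place_rng, n, sample_position, sigma_range, overlap_tol, max_tries=10 * max(n, 1)
    )
    canvas = np.full(shape, background, dtype=np.float64)
    for (r, c), s in zip(centers, sigmas):
        _add_blob(canvas, r, c, s, amplitude)
    canvas += noise_rng.normal(0.0, amplitude / snr, shape)
    grid = PixelGrid(_quantize(canvas), bit_depth=8, pd=pd)
    truth = pandas_.DataFrame(
        {
            "row": centers[:, 0],
            "col": centers[:, 1],
            "sigma": sigmas,
            "label": "nucleus",
        }
    )
    params = dict(
        kind="nuclei", n=n, gradient=gradient, shape=shape, snr=snr,
        sigma_range=sigma_range, amplitude=amplitude, background=background,
        overlap_tol=overlap_tol, center=center, disk_radius=radius, pd=pd,
    )
    return SyntheticScene(MultiChannelImage({"nuclei": grid}), truth, seed, params)


def gen_livedead_scene(
    n: int,
    live_frac: float,
    shape: tuple[int, int] = DEFAULT_SHAPE,
    seed: int = 0,
    snr: float = 10.0,
    radius_range: tuple[float, float] = (4.0, 8.0),
    amplitude: float = 180.0,
    background: float = 10.0,
    overlap_tol: float = 0.0,
    pd: float = 1.0,
) -> SyntheticScene:
    """Two-channel live/dead scene with Bernoulli(live_frac) labels.

    Cells are rendered as sharp-edged uniform disks (saturated
    fluorescence spots), live cells only in the ``live`` channel and dead
    cells only in the ``dead`` channel, over shared background noise.
    Sharp edges make the covered area insensitive to the exact threshold
    level, so the area ground truth is well defined.  Ground truth stores
    each cell's label and radius.
    """
    if not (0.0 <= live_frac <= 1.0):
        raise ValueError("live_frac must be in [0, 1]")
    place_rng, label_rng, noise_rng = _rngs(seed, 3)
    h, w = shape
    margin = radius_range[1] + 2

    centers = np.empty((n, 2))
    radii = np.empty(n)
    placed, tries = 0, 0
    max_tries = 10 * max(n, 1)
    while placed < n:
        if tries >= max_tries:
            raise PlacementError(
                f"placed only {placed}/{n} cells within {max_tries} tries"
            )
        tries += 1
        rad = place_rng.uniform(*radius_range)
        r = place_rng.uniform(margin, h - margin)
        c = place_rng.uniform(margin, w - margin)
        if placed:
            d2 = (centers[:placed, 0] - r) ** 2 + (centers[:placed, 1] - c) ** 2
            min_sep = (1.0 - overlap_tol) * (radii[:placed] + rad + 1.0)
            if np.any(d2 < min_sep**2):
                continue
        centers[placed] = (r, c)
        radii[placed] = rad
        placed += 1

    labels = np.where(label_rng.random(n) < live_frac, "live", "dead")
    channels = {}
    for name in ("live", "dead"):
        canvas = np.full(shape, background, dtype=np.float64)
        for (r, c), rad, lab in zip(centers, radii, labels):
            if lab == name:
                rr, cc = draw_disk((r, c), rad, shape=shape)
                canvas[rr, cc] = amplitude
        canvas += noise_rng.normal(0.0, amplitude / snr, shape)
        channels[name] = PixelGrid(_quantize(canvas), bit_depth=8, pd=pd)
    truth = pandas_.DataFrame(
        {
            "row": centers[:, 0],
            "col": centers[:, 1],
            "radius": radii,
            "label": labels,
        }
    )
    params = dict(
        kind="livedead", n=n, live_frac=live_frac, shape=shape, snr=snr,
        radius_range=radius_range, amplitude=amplitude, background=background,
        overlap_tol=overlap_tol, pd=pd,
    )
    return SyntheticScene(MultiChannelImage(channels), truth, seed, params)


def stratified_beta(
    alpha: float, beta: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Quantile-stratified Beta(alpha, beta) sample in random order.

    Inverse-CDF values at midpoints of n equal-probability strata: the
    sample moments track the analytic ones far more tightly than i.i.d.
    draws, which keeps distribution-level ground truth (e.g. skewness)
    sharp at modest n.
    """
    q = (np.arange(n) + 0.5) / n
    values = beta_dist.ppf(q, alpha, beta)
    rng.shuffle(values)
    return values


def gen_shape_scene(
    n: int,
    ecc_sampler,
    shape: tuple[int, int] = DEFAULT_SHAPE,
    seed: int = 0,
    a_range: tuple[float, float] = (12.0, 25.0),
    amplitude: float = 200.0,
    background: float = 30.0,
    noise_sigma: float = 3.0,
    blur_sigma: float = 1.0,
    min_gap: float = 6.0,
    pd: float = 1.0,
) -> SyntheticScene:
    """Filled rotated ellipses with a prescribed eccentricity distribution.

    ``ecc_sampler`` may be an explicit array of eccentricities (length
    >= n, used in order), a callable ``f(rng, size) -> array``, a frozen
    scipy distribution, or a single float.  Semi-major axes are uniform
    in ``a_range``; placements are non-overlapping with ``min_gap`` px of
    clearance so that the optical blur (``blur_sigma``) cannot bridge
    neighbouring cells.  Ground truth stores the analytic eccentricity of
    every generating ellipse.
    """
    place_rng, noise_rng = _rngs(seed, 2)
    if callable(ecc_sampler):
        eccs = np.asarray(ecc_sampler(place_rng, n), dtype=np.float64)
    elif hasattr(ecc_sampler, "rvs"):
        eccs = np.asarray(
            ecc_sampler.rvs(size=n, random_state=place_rng), dtype=np.float64
        )
    elif np.isscalar(ecc_sampler):
        eccs = np.full(n, float(ecc_sampler))
    else:
        eccs = np.asarray(ecc_sampler, dtype=np.float64)[:n]
        if eccs.size < n:
            raise ValueError("ecc_sampler array shorter than n")
    if np.any(eccs < 0) or np.any(eccs >= 1):
        raise ValueError("eccentricities must lie in [0, 1)")

    h, w = shape
    canvas_mask = np.zeros(shape, dtype=bool)
    rows = []
    placed: list[tuple[float, float, float]] = []
    tries = 0
    max_tries = 30 * max(n, 1)
    while len(rows) < n:
        if tries >= max_tries:
            raise PlacementError(
                f"placed only {len(rows)}/{n} ellipses within {max_tries} tries"
            )
        tries += 1
        a = place_rng.uniform(*a_range)
        ecc = eccs[len(rows)]
        b = a * np.sqrt(1.0 - ecc * ecc)
        theta = place_rng.uniform(0.0, np.pi)
        r = place_rng.uniform(a + 2, h - a - 2)
        c = place_rng.uniform(a + 2, w - a - 2)
        ok = True
        for pr, pc, pa in placed:
            if (r - pr) ** 2 + (c - pc) ** 2 < (a + pa + min_gap) ** 2:
                ok = False
                break
        if not ok:
            continue
        placed.append((r, c, a))
        rr, cc = draw_ellipse(r, c, a, b, rotation=theta, shape=shape)
        canvas_mask[rr, cc] = True
        rows.append(dict(row=r, col=c, a=a, b=b, theta=theta, ecc=ecc, label="cell"))

    img = np.where(canvas_mask, amplitude, background).astype(np.float64)
    if blur_sigma > 0:
        img = gaussian_filter(img, blur_sigma)
    img += noise_rng.normal(0.0, noise_sigma, shape)
    grid = PixelGrid(_quantize(img), bit_depth=8, pd=pd)
    truth = pandas_.DataFrame(rows)
    params = dict(
        kind="shapes", n=n, shape=shape, a_range=a_range, amplitude=amplitude,
        background=background, noise_sigma=noise_sigma, blur_sigma=blur_sigma,
        min_gap=min_gap, pd=pd,
    )
    return SyntheticScene(MultiChannelImage({"cytoskeleton": grid}), truth, seed, params)


def gen_wound_series(gt: KineticsGroundTruth, condition: str = "") -> WoundSeries:
    """Exponential closure series with multiplicative Gaussian noise.

    free(t) = y0 · e^(t/τ) · (1 + ε_t), ε_t ~ N(0, noise_sigma) for
    t > 0 (time 0 is the normalisation reference and stays exact); the
    normalised series is floored at 0.01%.
    """
    rng = np.random.default_rng(gt.seed)
    t = np.asarray(gt.times, dtype=np.float64)
    clean = gt.y0_true * np.exp(t / gt.tau_true)
    eps = rng.normal(0.0, gt.noise_sigma, t.size)
    eps[0] = 0.0
    noisy = clean * np.clip(1.0 + eps, 1e-4, None)
    return normalize_series(t, noisy / 100.0, condition=condition)


def render_wound_frame(
    free_frac: float,
    shape: tuple[int, int] = (512, 512),
    seed: int = 0,
    texture_mean: float = 120.0,
    texture_sd: float = 45.0,
    wound_sd: float = 2.0,
    pd: float = 1.0,
) -> PixelGrid:
    """Textured monolayer with a smooth central vertical stripe.

    The stripe (cell-free wound) covers ``free_frac`` of the width; the
    monolayer is high-variance pixel noise, the wound near-constant, so a
    local-texture detector can recover the fraction.
    """
    if not (0.0 <= free_frac <= 1.0):
        raise ValueError("free_frac must be in [0, 1]")
    rng = np.random.default_rng(seed)
    h, w = shape
    img = rng.normal(texture_mean, texture_sd, shape)
    stripe = int(round(free_frac * w))
    if stripe > 0:
        c0 = (w - stripe) // 2
        img[:, c0 : c0 + stripe] = rng.normal(texture_mean, wound_sd, (h, stripe))
    return PixelGrid(_quantize(img), bit_depth=8, pd=pd)


def gen_ct_table(
    true_folds: Mapping[str, float],
    n_reps: int = 3,
    noise_sigma: float = 0.2,
    seed: int = 0,
    refs: Sequence[str] = ("ACTB", "HPRT1"),
    control: str = "static",
    treated: str = "dynamic",
    ref_ct: float = 20.0,
    target_ct: float = 25.0,
) -> pandas_.DataFrame:
    """qPCR Ct table with known fold changes between two conditions.

    Reference Cts centre on ``ref_ct`` and control-condition target Cts
    on ``target_ct``; treated target Cts are shifted by −log2(fold) so
    that a noiseless table inverts exactly through the 2^−ΔΔCT report.
    """
    if any(f <= 0 for f in true_folds.values()):
        raise ValueError("true folds must be positive")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for condition in (control, treated):
        for rep in range(1, n_reps + 1):
            sample = f"{condition}_{rep}"
            for ref in refs:
                rows.append(
                    dict(sample=sample, condition=condition, gene=ref,
                         ct=ref_ct + rng.normal(0.0, noise_sigma))
                )
            for gene, fold in true_folds.items():
                base = target_ct
                if condition == treated:
                    base = target_ct - np.log2(fold)
                rows.append(
                    dict(sample=sample, condition=condition, gene=gene,
                         ct=base + rng.normal(0.0, noise_sigma))
                )
    return pandas_.DataFrame(rows)


def write_scene(scene: SyntheticScene, outdir: str | Path, name: str) -> None:
    """Write a scene's channels (TIFF), truth (CSV) and params (key=value)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for channel, grid in scene.channels.channels.items():
        save_image(grid, outdir / f"{name}_{channel}.tif")
    write_table(scene.truth, outdir / f"{name}_truth.csv")
    with open(outdir / f"{name}_params.txt", "w") as fh:
        fh.write(f"seed = {scene.seed}\n")
        for key, value in scene.params.items():
            fh.write(f"{key} = {value}\n")
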