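# Methods

This note documents the models, algorithms and numerical choices behind
`perfquant`, what the synthetic-data generators do and do not emulate,
and the known limitations of each read-out.

## Image model and conventions

All image operations act on a `PixelGrid`: a 2D array of 8- or 16-bit
intensities plus the physical pixel edge length `pd` (µm/px, strictly
positive).  Coordinates are (row, col), 0-based, row 0 at the top.
Pixel size is never read from file metadata — conversions routinely drop
or corrupt it — so it is a required user input, defaulting to 1.0 µm/px
with a logged warning (areas then come out in pixel units).  Colour
images split into `red`/`green`/`blue` channels; the caller aliases them
to their biological meaning (e.g. green → live).

Connected components are 8-connected everywhere: cells in dense
scaffold images frequently touch diagonally, and using one connectivity
throughout keeps counts and areas consistent between operations.

## Thresholding

Global thresholds operate on one-bin-per-integer-level histograms (256
or 65536 bins; 16-bit data is not rebinned) and return the largest
level `t` assigned to the background, with foreground strictly `> t`.
Both objectives are evaluated for every candidate split with both
classes occupied, via cumulative sums, which is numerically identical to
the brute-force scan the tests use as oracle; ties break to the
smallest level so results are deterministic.

* **Otsu**: maximises the between-class variance
  `w0·w1·(µ0 − µ1)²`.  Used for nuclear (DAPI) segmentation.  Note the
  objective is nearly flat across a wide inter-mode gap, so the exact
  argmax between well-separated modes is data-noise dependent — any
  value in the gap separates the classes equally well.
* **Maximum entropy (Kapur–Sahoo–Wong)**: maximises the sum of Shannon
  entropies of the two normalised sub-histograms.  Zero-count levels
  contribute nothing; candidate splits must leave both classes
  non-empty (an empty class would otherwise trivially "win" with zero
  entropy).  Used for live/dead area segmentation.
* **Adaptive threshold**: foreground iff
  `value > local_mean × (2 − s)`, with the local mean over an odd
  square window (default: 1/8 of the shorter image side, rounded up to
  odd) under replicate border padding.  The sensitivity `s ∈ [0, 1]`
  maps to an acceptance factor between 2 (strict) and 1 (lenient), so
  foreground grows monotonically with `s`; the cytoskeleton pipeline
  uses the high-sensitivity setting s = 0.9 (factor 1.1).  This
  semantics is one of several in circulation for "sensitivity"; it was
  chosen because it is monotone, dimensionless, and reduces to plain
  local-mean thresholding at s = 1.

## Morphology and object descriptors

The nuclear pipeline opens the Otsu mask with a diamond (L1-ball)
structuring element.  The reference recipe names a "height 6 pixels"
diamond; a symmetric diamond has odd extent, so radius 3 (vertical
extent 7 px) is used as the closest symmetric element and the radius is
exposed as a parameter (radius 2, extent 5, is the other nearby proxy).
Note that opening with a diamond is not shape-preserving for rectangles:
it chamfers a small L1 triangle off each convex corner.

Object descriptors come from second-order moments of the pixel
coordinates: with eigenvalues λ₁ ≥ λ₂ of the 2×2 coordinate covariance
(ddof 0), the equivalent-ellipse semi-axes are `a = 2√λ₁`, `b = 2√λ₂`
and the eccentricity `E = √(1 − b²/a²)`.  Single-pixel objects get
a = b = E = 0; a one-pixel-wide line has b = 0 and hence E = 1 exactly.
Moments were preferred over fitted bounding ellipses because they are
parameter-free, rotation-equivariant and reproducible.

**Accuracy limit near circularity.**  E has unbounded derivative in
λ₂/λ₁ at 1, so for near-circular rasterised objects the binary-moment
estimate carries an irreducible error of order 0.04–0.12 (a digitised
disk of radius 20 can measure E ≈ 0.1).  Measured on rasterised
ellipses across orientations and sub-pixel centres, the error is below
0.02 once E ≥ 0.7 for a ≥ 10 px, or E ≥ 0.5 for a ≥ 15 px.
Consequences: per-cell E is trustworthy for elongated cells;
distribution summaries over populations containing round cells inherit
a positive floor that inflates skewness in *both* conditions being
compared.  On a constructed +35% skewness shift the pipeline recovers
an increase of roughly +28–35% — ratios are compressed by a few points
but condition ordering and effect size are preserved.

The morphometry pipeline is: adaptive threshold → remove objects with
area < 50 px (8-connected) → fill holes (background components not
reaching the border) → label and compute E.  The summary reports the
sample skewness (adjusted Fisher–Pearson, `g1·√(n(n−1))/(n−2)`) and the
fraction of cells with E above 0.8 (configurable cutoff).

## Viability areas

Each live/dead channel is independently thresholded with the
maximum-entropy criterion and the covered area quantified as
`A = np · pd²`.  Condition comparisons use the ratio of arithmetic
means of per-image areas plus a two-sided Mann–Whitney test.  The
analysis quantifies area, not per-cell viability — overlapping or
saturated spots are counted by the pixels they cover.

## Spatial distribution

Nuclei counts come from Otsu → diamond opening → labeling.  Two region
modes are supported, because how edge and core fields of view are
delimited is an acquisition choice:

1. pre-cropped per-region images (one count per image; the default CLI
   mode), and
2. automatic assignment: the scaffold boundary is estimated as the
   convex hull of object centroids, the centre as the hull centroid
   (user-overridable), and an object is "core" when its centre distance
   is below 50% (configurable) of the boundary distance along its own
   ray.

The edge/core contrast is reported as
`100 · (mean_edge − mean_core) / mean_edge`, anchored to the edge mean
(the larger group in diffusion-limited scaffolds), with a
Kruskal–Wallis test across regions.  Radial profiles bin centroid
distances into equal-width annuli around the centre; under spatial
uniformity, expected counts are proportional to annulus area.

## Wound-closure kinetics

`detect_free_area` computes the local standard deviation over an odd
window (default 15 px), quantises the map to 256 levels, and applies
the Otsu threshold; the cell-free fraction is the low-texture share of
the frame.  Local standard deviation is invariant to global intensity
offsets.  A fully confluent frame has a unimodal texture map on which
any global threshold is meaningless, so a bimodality guard requires the
low class's mean deviation to be under half the high class's; otherwise
the frame is reported as having no detectable wound (fraction 0).

Series are normalised to the time-0 wound
(`free_pct = 100 · fraction(t)/fraction(0)`) and fully closed
observations are floored at 0.01% so the model remains defined on the
log scale.

The closure model is the two-parameter exponential
`y(t) = y0 · e^{t/τ}` with τ < 0 enforced (parameterised internally by
the rate k = 1/τ ≤ 0).  Data near closure approach zero, so no plateau
term is included by default; a plateau variant (`+ c`) and a
y0 = 100-constrained variant exist for sensitivity analysis.  Fitting
is unweighted nonlinear least squares (no replicate heteroscedasticity
information is assumed), started from a log-linear pre-fit with a few
rate-scaled restarts, and tight tolerances so fits are invariant to
time-unit rescaling to ~1e-6 relative.  The 95% CI on τ is the
Student-t interval on k from the asymptotic covariance (df = n − p),
transformed to τ — this produces the asymmetric intervals typical of
curve-fitting software.  If the CI on k touches 0, the upper τ bound is
reported as −∞ and the fit is flagged; an increasing series drives k to
the boundary and raises a warning (τ → −∞, no closure).  R² is
computed against the mean-only model, and `T50 = −τ · ln 2` identically.

With the study's five sampling times (0/4/6/8/24 h) and 5%
multiplicative noise, the fitter recovers τ ∈ [−30, −5] h with a median
relative error under 10% and ~90–95% CI coverage (verified over 100
seeded series).  Fits can be made to per-timepoint means or to all
replicate observations; `compare_conditions` additionally runs a
Mann–Whitney test at each shared time point and reports the τ ratio.

## Relative expression (2^−ΔΔCT)

Per sample, `ΔCT = Ct_target − mean(Ct_refs)` (arithmetic mean of the
reference Cts, i.e. geometric-mean normalisation on the expression
scale; the package uses ACTB + HPRT1 by default but accepts any
reference set).  `ΔΔCT` is the difference of group means of ΔCT and the
fold is `2^−ΔΔCT`, with amplification efficiency fixed at 2 (no Pfaffl
correction).  Mann–Whitney runs on the per-replicate `2^−ΔCT` values.
Ct values outside [1, 45] are rejected as data errors.

Error propagation worth knowing: with per-measurement noise σ (cycles),
two references and n replicates per condition,
`sd(ΔΔCT) = σ·√(3/n)`.  At the common σ = 0.2, n = 3 this is 0.2
cycles, i.e. ~±15% (1σ) on the fold — single-experiment folds for
small effects (≤1.3×) are inherently noisy at this design, which is why
the acceptance report averages folds over simulated replicate
experiments.

## Synthetic-data generators

Generators emulate the statistical structure each analysis assumes, not
microscope optics: no PSF beyond an optional Gaussian blur, no shading,
no autofluorescence, no touching-cell clumps, no 3D sectioning.
Passing tests therefore certify the *computations* (segmentation
arithmetic, counting, moment descriptors, fitting, ΔΔCT algebra) under
controlled truth — they do not certify segmentation robustness on real
micrographs.

* **Nuclei** (`gen_nuclei_scene`): Gaussian blobs (σ ∈ [3, 6] px,
  amplitude 180 on background 20) at rejection-sampled positions in the
  inscribed disk; the radial density rises linearly to `gradient`×
  the central density at the rim.  `snr` = amplitude / noise sd.  Up to
  10% footprint overlap is allowed (nuclei do crowd); the retry budget
  is 10·n candidates, beyond which a `PlacementError` is raised.  At
  SNR ≥ 5 the Otsu + opening pipeline recounts 200 nuclei within 5%.
* **Live/dead** (`gen_livedead_scene`): sharp-edged uniform disks
  (radius ∈ [4, 8] px) assigned to one channel by Bernoulli(live_frac).
  Disks rather than Gaussian spots: a sharp edge makes the covered area
  insensitive to the exact threshold level, so the area ground truth is
  well defined (threshold level shifts with foreground density, which
  would otherwise bias area fold changes between dense and sparse
  conditions by ~10%).
* **Shapes** (`gen_shape_scene`): filled rotated ellipses, semi-major
  axis ∈ [12, 25] px (the lower bound keeps every object above the
  50-px area filter at any eccentricity), amplitude 200 on background
  30, Gaussian blur σ = 1 (optics), noise σ = 3, and ≥ 6 px clearance
  between cells so blur cannot bridge neighbours.  The eccentricity
  sampler accepts arrays, callables, frozen distributions or a scalar;
  `stratified_beta` provides quantile-stratified Beta samples whose
  sample moments track the analytic ones tightly at modest n — used
  whenever distribution-level truth (e.g. skewness) must be sharp with
  only a few hundred renderable cells.
* **Wound** (`gen_wound_series` / `render_wound_frame`): series follow
  `y0·e^{t/τ}·(1 + ε)`, ε ~ N(0, σ) for t > 0 (t = 0 is the
  normalisation reference and stays exact), floored at 0.01%; frames
  are high-variance pixel noise (confluent texture) with a
  near-constant central stripe covering the cell-free fraction.
* **Ct tables** (`gen_ct_table`): reference Cts ~ N(20, σ), control
  targets ~ N(25, σ), treated targets shifted by −log2(fold); a
  noiseless table inverts exactly through `expression_report`.

All generators derive independent substreams from the top-level seed
(`SeedSequence.spawn`), render in float and quantise to the image bit
depth, and are bit-reproducible under a fixed seed.  Defaults:
1024×1024 px, 8-bit, pd = 1.0 µm/px.

## Statistical tests

Exact small-sample nulls are computed by enumerating every split of the
pooled (possibly tied) observations: Mann–Whitney and KS when both
groups have ≤ 10 observations, Kruskal–Wallis when the pooled sample
has ≤ 8.  Two-sided Mann–Whitney p is `2·min(P(U ≤ u), P(U ≥ u))`
capped at 1.  Large samples use the tie/continuity-corrected normal
approximation (MW), the χ²_{k−1} tail with tie correction (KW), and the
asymptotic Kolmogorov distribution (KS).  All-identical data returns
H = 0, p = 1 rather than an error.

## Problem sizes used in validation

Unit and acceptance tests run on scenes of 512²–1024² px with 60–500
objects, 4–12 images per condition, 100 seeded kinetics series and
10–16 simulated qPCR experiments — sizes at which the statistical
bands being asserted (5% count recovery, ±10-point region contrast,
[20%, 50%] skewness-increase window, ~15% per-experiment fold noise)
are meaningful without making the suite slow.

## Known limitations

* Touching or overlapping cells are not split (no watershed); counts
  assume the opening separates or removes fused detections.
* Eccentricity near circularity carries the moment-estimator floor
  described above; comparisons of skewness between conditions are
  slightly compressed.
* The wound detector certifies only against synthetic texture; real
  phase-contrast wound edges (debris, partial confluency) are harder.
* The exponential closure model has no plateau by default and does not
  separate migration from proliferation.
* No efficiency-corrected qPCR model; folds assume perfect doubling.
* 2D only: no z-stacks, registration or volumetric morphology.
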