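# Methods

This note records the models, conventions and numerical choices behind
`clutchmap`, in the spirit of a methods appendix: what is computed, under
which assumptions, and where a genuinely open design decision was made.

## Input model and pre-processing

A localisation table is one row per blink: frame ≥ 1, x/y in nm, intensity in
photons, localisation uncertainty and fitted PSF sigma in nm. Tables are
assumed drift-corrected upstream; `clutchmap` performs no localisation
fitting or drift correction. Quality filtering keeps blinks with intensity in
[300, 5000] photons, uncertainty ≤ 35 nm and sigma ≤ 200 nm. All bounds are
**inclusive** — the thresholds are stated in the literature as ranges without
open/closed qualifiers, and inclusivity only matters on a measure-zero set.

The nucleus outline is a simple closed polygon in nm (in real use, a manual
segmentation of the 16 nm/pixel reconstruction; here, a generated shape).
Blinks outside the polygon are discarded; points exactly on the boundary are
kept (closed-set convention, maximising retention). Rasterisation uses
0-based half-open pixels of 16 nm with the origin at the ROI bounding-box
minimum, so a blink at exactly one pixel width lands in pixel 1, not 0.

## Density homogenisation

Blink yield varies strongly between acquisitions, which biases any
density-based clustering. Each nucleus is reduced to a common global density
(default 0.001 blinks/nm²) by keeping only blinks from the last *k* frames.
*k* is chosen by exhaustive scan over all suffixes, minimising the absolute
deviation |count/area − target|; the scan never assumes unimodality of the
deviation in *k*. Ties go to the smallest *k*, i.e. the latest-only suffix,
because late frames avoid the unstable early acquisition phase. Whether the
historical analyses minimised absolute or relative deviation is not
documented; at a fixed target the two argmins coincide, and absolute
deviation was chosen. A nucleus is *accepted* when the best relative
deviation is ≤ 10% (configurable; the underlying "failed to approach the
target" criterion is not quantified anywhere, so the 10% default is this
package's choice, echoed in every output record). Rejected nuclei are
reported, flagged, and excluded from group statistics — never silently
dropped.

## Three-tier segmentation

1. **Denoising.** DBSCAN with ε = 60 nm and min points = 10 labels sparse
   blinks as noise; every non-noise blink is retained regardless of its
   cluster label. The classical convention is used: a point is core when at
   least min_pts points *including itself* lie within ε (this matches
   scikit-learn; the test oracle implements the same convention
   independently).
2. **Clutches.** Complete-linkage hierarchical clustering of the denoised
   blinks, cut at a maximum intracluster distance of 160 nm; clusters with
   fewer than 10 blinks are discarded. Complete linkage is the only linkage
   for which the cut is a hard guarantee that every cluster's maximum
   pairwise blink distance is ≤ 160 nm — a "maximum intracluster distance"
   semantics that single or average linkage would not honour. Clutches whose
   blink density is below 5× the nucleus's global (post-homogenisation)
   density are filtered out, as are clutches with a degenerate boundary
   (area below one 16 nm pixel's inscribed disc, π·16² nm²) — logged, since
   a "structure" smaller than a reconstruction pixel is not interpretable.
3. **Aggregates.** Clutches are chained into chromatin aggregates when the
   minimum blink-to-blink distance between them is ≤ 30 nm. DBSCAN over
   clutch units with min points = 1 degenerates to single-linkage connected
   components at ε, and is implemented as exactly that (KD-tree accelerated;
   the tests require equality with an all-pairs union-find oracle). Every
   clutch belongs to exactly one aggregate; singletons are allowed.

Blinks that survive denoising but end up in no retained clutch stay in play
for nucleus-level statistics (periphery z-score, RDF, H) and are excluded
from clutch/aggregate statistics; blink-level and structure-level measures
are computed on different strata. Density-filtered clutches do not re-enter
aggregate grouping. Output is independent of input row order; clutch and
aggregate identities are canonicalised by their smallest member index.

## Morphometrics

* **Periphery z-score.** Each blink's Euclidean distance to the nearest
  polygon edge, z-scored against the mean and SD of that distance over "all
  possible locations" in the nucleus, realised deterministically as the
  16 nm interior pixel grid (matching the reconstruction resolution). A
  Monte-Carlo reference (uniform interior points) is available behind a
  flag; the two agree to well under the reported precision. Negative mean ⇒
  peripheral (lamina-proximal) enrichment; uniform patterns average 0.
* **Structure boundaries** are alpha shapes, not convex hulls: Delaunay
  triangles are kept when their circumradius is at most a threshold, and the
  threshold is the smallest candidate (binary search over the sorted
  circumradii, exploiting that feasibility is monotone in practice and
  always holds at the convex-hull limit) for which the kept triangles union
  to a single polygon covering all member blinks. This makes the boundary
  parameter-free and reproducible. Degenerate inputs (< 3 distinct points or
  collinear) get area 0 and are flagged.
* **Approximate diameter** of an aggregate is the equivalent-circle diameter
  2·√(area/π); a maximum-caliper alternative was considered and rejected as
  the default because it is dominated by single outlying blinks.
* **Clutch proximity** is the mean of each clutch's boundary-to-boundary
  distances (0 when polygons overlap) to its min(10, n−1) nearest clutches,
  with neighbour *ranking* also by boundary distance. Undefined for a single
  clutch (flagged missing).
* **Per-nucleus summary:** blink- and clutch-level items are unweighted
  means; aggregate items (diameter, % nuclear area occupied, density) are
  means weighted by aggregate blink counts, so large structures dominate the
  way they dominate the underlying signal mass. With equal weights the
  weighted and unweighted means coincide (asserted in tests). Clutch density
  uses the clutch's own boundary area.

## Spatial statistics and border correction

All three statistics are edge-corrected by **minus-sampling against the
actual nuclear boundary**, per tested distance: at radius r, only blinks
whose distance to the polygon edge is ≥ r act as reference points, so every
counting disc lies fully inside the window. This keeps far more references
than excluding everything within the *maximum* tested distance of a bounding
rectangle, and needs no isotropic pair weighting. The per-radius reference
count is reported alongside every bin; bins with no references are NaN
rather than extrapolated.

* **RDF.** g over the annulus [r1, r2) is the mean over references (boundary
  distance ≥ r2, guaranteeing the *whole annulus* is interior) of
  count/(λ·π(r2²−r1²)), λ = n/area. Grid 0–500 nm, 10 nm steps.
* **H-function.** K̂(r) = area/(n−1) · mean over references of the count of
  other blinks within r; H = √(K̂/π) − r, zero under CSR. An uncorrected
  variant (all blinks as references) exists purely for comparison; on
  star-shaped windows it drifts ~25 nm negative at r ∈ [400, 500] nm where
  the corrected estimator stays within ~1 nm of zero (see
  `analysis/03_csr_calibration.py`).
* **F-function.** Empty-space CDF from 10,000 uniformly drawn evaluation
  points on a 16 nm distance grid (the reconstruction pixel size), computed
  on continuous coordinates rather than rasterised label images — the
  difference from a pixel-based computation is bounded by one pixel.
  The **deviation from randomness** compares the observed F with the mean F
  of 25 same-size uniform redraws of the centre pattern (fresh evaluation
  points and centres per shuffle, seeds derived from the master seed by
  fixed offsets): the trapezoidal integral of (F̄_random − F_observed) from 0
  to the first grid point where both curves reach 0.999 (an explicit,
  configurable stopping rule; the integration range of the historical
  implementation is undocumented). Positive ⇒ clustered, negative ⇒ regular.
  The default input is clutch centres; raw blinks are accepted too.

## Synthetic data: what it emulates, and what it does not

The generator exists because no localisation data for this assay are
deposited; it produces the *structures the pipeline claims to measure* with
exact ground truth.

* **Nuclei** are star-convex polygons: radius(θ) = R·(1 + a·f(θ)) with f a
  random low-order (k = 2–6) Fourier series normalised to max |f| = 1 and
  a < 1, guaranteeing simplicity. Defaults R = 5 µm, a = 0.3, 64 vertices.
  Real nuclei need not be star-convex; the shapes are adequate to exercise
  border corrections, not a morphological model.
* **CSR fields** draw a Poisson(density·area) count and place points by
  bounding-box rejection sampling (bounded retries). Calibration: the
  nearest-neighbour distance distribution at n ≈ 10⁴ matches the theoretical
  CSR form within a KS statistic of 0.02.
* **Clutch patterns** place blinks uniformly in discs of radius 40 nm
  (30 blinks each by default — the scale of nucleosome clutches). Without
  aggregation, centres keep ≥ 2·(clutch radius + 160 nm) mutual separation
  and 2·radius from the boundary so the segmentation ground truth is
  *provably unambiguous* and recovery tests can demand exactness. With an
  `aggregation_radius`, centres scatter around n_clutches//4 aggregate
  seeds — the single knob for generating ordered clustering levels.
  Background blinks are CSR and make up a stated fraction of the total.
* **Radial bias** accepts uniform candidates with probability
  (1 − d/d_max)^γ (d = boundary distance): γ = 0 is exactly CSR, larger γ
  concentrates signal perinuclearly; the mean periphery z-score decreases
  monotonically in γ (≈ 0 / −0.40 / −0.78 at γ = 0/1/3).
* **Frame stamping** assigns frames from a uniform or front-loaded profile
  and fills photometric columns from plausible dSTORM distributions
  (lognormal photons around 10³; uncertainty ≈ 15 ± 5 nm; sigma ≈ 150 ±
  20 nm). There is no photophysics: no blinking kinetics, no PSF or
  localisation-error model, no drift. Passing tests therefore demonstrate
  the *analysis chain* is correct and calibrated — not that the generator
  reproduces microscope data. Localisation uncertainty in real data blurs
  clutch boundaries; measured radii there include that blur, and generator
  recovery being exact does not bound that effect.

Determinism: every sampling call takes an explicit seed for its own
`numpy.random.Generator`; identical specs and seeds reproduce outputs
bit-for-bit, and pipeline reruns produce byte-identical CSVs.

## Problem sizes and runtime choices

Null-calibration runs use an irregular 5 µm nucleus at the working density
(≈ 8·10⁴ blinks) over 10 seeds — large enough that per-bin Monte-Carlo error
on the RDF is ~10⁻³. Pair counting is KD-tree based and shared between RDF
and H via a distance × boundary-bucket histogram (`pair_histogram`), making
a full calibration run a few seconds per seed. Oracle-equivalence suites use
≥ 100 random instances per operation at n ≤ 300, where the naive O(n²)–O(n³)
references are still fast. The simulated cohort uses 1.6 µm nuclei
(≈ 10⁴ blinks each), the size at which complete linkage's quadratic memory
stays trivial.

## Known limitations

* 2-D only; optical sections of 3-D nuclei are analysed as planar patterns.
* One colour channel at a time; no bivariate (cross-mark) statistics.
* The alpha-shape threshold search assumes feasibility is monotone in the
  circumradius threshold; a pathological point set could in principle make
  the binary search return a valid but not strictly minimal threshold (the
  result is always a single all-covering polygon).
* Group comparison is descriptive (mean ± SEM per group); inferential
  statistics are deliberately out of scope.
* Homogenisation equalises the *global* density only; sub-nuclear density
  gradients are untouched, by design.
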