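# Methods

This note documents the models, algorithms and design choices behind
`hairmorph`, the assumptions they rest on, and what the simulation-based
validation does and does not establish.

## Curvature pipeline

**Model.** A washed hair fragment cut to a few millimetres and allowed to
settle flat expresses its intrinsic curvature in 2-D, and over that length
is well approximated by a circular arc. Curvature is therefore defined as
the inverse radius (mm⁻¹) of the circle best fitting the fragment's
centerline; a straight fragment has curvature 0. This breaks down for
fragments long enough to show varying curvature or helical lift-off — the
protocol assumption is short fragments lying flat.

**Stages.**

1. *Ridge enhancement* — Meijering's Hessian-eigenvalue neuriteness filter
   (`skimage.filters.meijering`, `black_ridges=True`) responds maximally
   along dark curvilinear structures on a light background. The scale
   should match the stroke half-width: the default single scale of 2 px
   suits ~5 px-wide fibers at 132 px/mm; pass several scales
   (`CurvatureOptions.ridge_sigmas`) for heterogeneous fiber widths.
2. *Binarization and cleaning* — Otsu threshold on the ridge response,
   intersected with the dark pixels of the original image (Otsu again).
   The intersection matters: the ridge response bleeds ~2σ past fragment
   ends, and gating by intensity restores the true extent, which would
   otherwise inflate length estimates by several percent. Polarity is
   auto-detected (if the "dark" phase covers >50% of the image the image is
   taken as light-on-dark and inverted). Specks ≤16 px and holes ≤16 px
   are removed (`speck_area_px`, `hole_area_px`).
3. *Skeletonization and splitting* — Zhang–Suen thinning
   (`skimage.morphology.skeletonize`) to 1 px width; skeleton pixels with
   more than two neighbors (branch points, from touching or crossing
   fibers) are deleted together with their 8-neighborhood, so each
   remaining component is a simple path. Paths shorter than 16 px
   (~0.12 mm at 132 px/mm; `min_length_px`) are dropped. A crossing
   therefore contributes its arms as separate fragments rather than one
   merged trace that would corrupt the circle fit.
4. *Length* — the traced path's chain-code length, axial steps weighted 1
   and diagonal steps √2, multiplied by Kulpa's calibration factor
   π(1+√2)/8 ≈ 0.948. The raw √2 rule systematically overestimates the
   length of a digitized smooth curve by ~5% when averaged over
   orientations; the calibration removes that bias (verified on the
   simulators: per-image mean length within ~0.7% of truth, vs ~+5%
   uncalibrated). The uncalibrated rule remains available as
   `length_calibration="chain"`. Because the calibration is exact only on
   average over orientations, individual fragment lengths still vary by
   ±2–3%; per-image means over ~25 fragments are accurate to a few tenths
   of a percent.
5. *Curvature* — Taubin's algebraic circle fit (smallest singular vector of
   the centered design `[z − z̄, u, v]`; near-unbiased on partial arcs),
   followed by a Gauss–Newton orthogonal-distance refinement. By default
   the fit uses *all* pixels of the fragment's binary component rather than
   the skeleton (`fit_on="component"`): the stroke's two edges carry most
   of the localization information, and fitting the full band roughly
   halves the per-fragment variance. Fitting a solid band biases the
   radius upward by w²/3R (w = stroke half-width), which is removed in
   closed form as `R ← R − var(d)/R` since var(d) estimates w²/3.
   Numerically collinear input (straight hair) is flagged degenerate and
   reported as curvature 0, not dropped — straight is a valid phenotype.

**Error behaviour.** On simulated arcs the per-fragment curvature error is
dominated by boundary digitization, falling from ~1.5% (relative, SD) at
0.1 mm⁻¹ (a 9° arc of a 10 mm circle) to ~0.05% at 2 mm⁻¹ (a 180° arc);
per-image means over 25 fragments are 5× tighter. Across the 0.1–2 mm⁻¹
study grid this yields RMSE of a few ×10⁻⁴ mm⁻¹ and estimated-vs-true
r² > 0.9999.

## Section pipeline

1. *Crop* — coarse Otsu threshold, largest dark blob, square crop centered
   on its centroid with a 25 px margin (or a fixed `--crop-size`). Cropping
   is what keeps Chan–Vese tractable on large canvases.
2. *Segmentation* — Chan–Vese two-phase piecewise-constant active contour
   (`skimage.segmentation.chan_vese`) on intensities normalized to [0, 1]:
   smoothing weight µ = 0.25, equal data weights, checkerboard
   initialization, tolerance 10⁻³, at most 200 iterations, dt = 0.5 (all in
   `ChanVeseParams`). The energy is region-based, so it tolerates the soft
   edges of real section micrographs. The *darker* phase is taken as the
   section — an area-based polarity rule fails when the section fills most
   of the crop. Only the largest connected region is retained (debris
   rejection) and its holes (e.g. an unstained medulla) are filled. On
   large high-contrast crops the level-set jitter often stays above the
   tolerance without changing the segmentation; the mask is returned with
   `converged=False` in that case. A uniform or foreground-filling result
   raises a no-section error, and batch runs skip such files with a log
   entry.
3. *Measures* — `skimage.measure.regionprops`: area = pixel count / ρ²;
   min/max diameter = minor/major axis lengths of the moments-equivalent
   ellipse / ρ; eccentricity from those axes as √(1 − (b/a)²), so the
   reported eccentricity and diameters are mutually consistent. Feret
   diameters were deliberately not used: with moment axes, the a and b in
   the eccentricity formula are exactly the reported radii. A single-pixel
   region reports eccentricity 0.

Calibration ρ (px/µm) must be supplied by the user for real micrographs —
it is a property of the microscope and camera, not of the file.
One-section-per-image is assumed (the largest region wins); multi-section
chips should be imaged or cropped per section.

## Ground-truth simulators

The simulators generate the package's own validation data; they emulate
idealized, binary-contrast versions of the real imaging targets.

*Arcs.* Each image holds `n_fragments` (default 25) arcs of one curvature
c at random orientations on a 5200×3900 px canvas at 132 px/mm — one
simulated "individual" per image. The start angle is uniform on (0, π) and
the sweep is π/(2r) radians (r = 1/c in mm), making every arc's true length
exactly π/2 mm regardless of curvature; 25 sample points along each arc are
exposed via `arc_points` (x = r·cosθᵢ, y = r·sinθᵢ). Placement is
rejection sampling with a 10 px clearance between stroke bounding boxes
(the analysis assumes non-touching fragments). Strokes are rasterized
*analytically*: a pixel is foreground iff its center lies within half the
stroke width (5 px total) of the continuous arc, with round end caps, drawn
binary (no anti-aliasing) so the truth table is unambiguous. Two rejected
alternatives are worth recording: rasterizing straight chords between the
25 sample points biases the drawn object's true curvature upward at high
curvature (chord sagitta; +0.13% at 2 mm⁻¹), and stamping a disk along a
Bresenham polyline produces ragged, orientation-correlated stroke edges
that inflate per-fragment curvature noise about six-fold. Analytic
rasterization keeps the drawn centerline exactly on the nominal circle and
the stroke edges clean digitizations of circles — the ground truth then
means what the truth table says.

*Ellipses.* One filled dark ellipse per image, centered: maximum diameter
~ U(50, 120) µm, eccentricity ~ U(0, 1) (fixing the minimum diameter),
rotation ~ U(0°, 360°), at 4.25 px/µm, drawn with `skimage.draw.ellipse`
(pixel-center membership). The truth table stores the analytic diameters,
area πab and eccentricity.

Both generators are seed-deterministic (bit-identical images and truth
tables for equal seeds). They do **not** simulate hair texture, medullas,
crossing or touching fragments, illumination gradients, defocus or camera
noise — so passing validation establishes the correctness and digitization
floor of the measurement chain, not robustness to messy real images.
Real-image performance rests on the pipeline's design margins (ridge
filtering, cleaning, branch splitting), not on these tests.

A note on the eccentricity validation metric: with eccentricity drawn
uniformly on (0, 1), some truths fall below the digitization floor (an
axis difference of ~0.1 px cannot be expressed by a binary raster — a
drawn ellipse of eccentricity 0.007 at these sizes *is* a digitized
circle). Such draws contribute ~100% relative error no matter how good the
measurement, so the mean per-ellipse relative error is a heavy-tailed,
draw-dependent statistic: ~1% in realizations without near-circular draws,
several percent otherwise. The absolute scale (RMSE ≈ 1.4×10⁻³) and
r² (> 0.9999) are the stable accuracy summaries.

## Validation metrics

RMSE = √(Σ(x̂ᵢ−xᵢ)²/n); percent error = mean per-element relative error
|x̂ᵢ−xᵢ|/xᵢ × 100 (zero truths excluded with a warning), with an
RMSE-normalized-by-mean-truth alternative (`mode="rmse_norm"`) as a
sensitivity check when truths approach zero; r² = squared Pearson
correlation (NaN, flagged, when n < 2 or variance is zero — e.g. length
truth, which is the same constant for every image). Validation joins
estimates to truth on `image_id` (the filename stem) and compares
*per-image means* to truth, matching the study design of one simulated
individual per image.

## Stratification demonstration

Synthetic cohorts stand in for a real admixed sample (such data are
restricted); the generator reproduces the qualitative structure such
samples show, with these defaults (all in `CohortConfig`):

* ancestry proportion z ~ ½·Beta(2,5) + ½·Beta(5,2) — bimodal, spanning
  [0, 1];
* curvature = 0.2 + 1.2·z, eccentricity = 0.45 + 0.25·z (clipped to
  [0, 0.99)), melanin index = 30 + 40·z, each plus Gaussian noise with SD
  c₀ + c₁·z (heteroscedastic: trait variance grows with African ancestry;
  scales 0.05+0.25z, 0.03+0.07z, 2+6z respectively);
* direct eccentricity→curvature effect = 0 by default, so any marginal
  correlation between the two is pure stratification.

The effect and noise scales are illustrative (chosen once to give curvature
spanning roughly 0.2–1.5 mm⁻¹ and clearly ancestry-driven traits at
n = 140), not calibrated to any real cohort. With them, the marginal
curvature–eccentricity association is significant (two-sided α = 0.05) in
essentially all cohorts of n = 140, and the ancestry-adjusted association
in ~α of them; an injected direct effect of 1 mm⁻¹ per unit centered
eccentricity is recovered with ~96% power (0.5 gives ~54% — effect sizes
below the noise scales are not reliably detectable at this n).

Machinery: OLS via statsmodels; quadratic form y = α + β₀x + β₁x² for the
curvilinear marginal relationship; ancestry adjustment either as a
covariate (y = α + β₀x + β₁z) or by the residual-on-residual construction
(each trait regressed on ancestry, residuals associated). Heteroscedastic
weighting refits by WLS with weights 1/ŷᵢ² from the unweighted pass;
with constant first-pass fitted values this reproduces OLS exactly.
Curvature binning into ordinal curl classes takes user-supplied strictly
increasing thresholds (half-open intervals, value at a threshold → upper
bin); the conventional thresholds come from external published work and
are deliberately not hard-coded.

## Numerical and degenerate-input conventions

* Coordinates are (row, col), origin top-left, 0-based, everywhere.
* Taubin fit: < 3 points is an error; collinear points give a degenerate
  result (infinite radius), not an exception; the Gauss–Newton polish stops
  at 15 iterations or a 10⁻¹⁰ step.
* Empty images yield hair_count 0 with NaN summaries; empty masks raise on
  measurement; unreadable files in batch runs are logged and skipped,
  never aborting the batch.
* Batch outputs are sorted by filename; reruns on identical inputs are
  byte-identical. Seeds derive all randomness; `run_metadata.json` records
  configuration and seed next to every CLI output.

## Problem sizes used by the shipped studies

The acceptance script runs the curvature study at the full 5200×3900 px
canvas and the ellipse study with each ellipse on a 1024×1024 px canvas
(sections are ≤510 px across and centered; the pipeline crops to the
section, so the larger canvas would only add I/O). The pytest acceptance
fixtures run the same 20-curvature × 25-fragment and 100-ellipse designs on
a 1950×2600 px canvas and 700 px canvases respectively — placement density
and measurement geometry are unchanged; only empty canvas area is smaller.

## Known limitations

* 2-D curvature only; fragments that lift out of plane, overlap, or curve
  non-circularly are outside the model. Crossing fibers are split, which
  is robust but discards the crossing region's pixels.
* Length estimates carry the ±2–3% per-fragment orientation dependence of
  calibrated chain codes; rely on per-image means.
* Chan–Vese assumes a two-phase intensity model; stained debris larger
  than the section, or multiple sections per image, violate the
  largest-region assumption.
* The stratification module demonstrates a statistical phenomenon on
  synthetic data; it makes no empirical claim about real cohorts.
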