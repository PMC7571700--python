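# Methods

This note documents the quantification model, its tunable parameters, the
synthetic world used for validation, and the numerical/design choices that
were genuinely open.

## Coordinate and time conventions

Images are `(C, T, Z, Y, X)` with pixel centers at integer indices,
`x = column`, `y = row`. Contours are converted to micrometres before any
differential quantity, so curvature carries physical units (1/µm). Frame
times are reported relative to `t0_frame`, the frame at which meiosis I ends
(defined in live imaging by the retained chromosomes visibly separating);
times before that are negative. When `t0_frame` is unset, times are relative
to the first frame and the provenance record says so.

## Membrane contour pipeline

1. **Plane choice.** Analysis runs on a single central z-plane, chosen as the
   plane with maximal total membrane-channel intensity (overridable).
2. **Segmentation.** Gaussian smooth (default σ = 2 px), Otsu threshold,
   morphological closing (disk 3), hole filling, largest connected component.
   Errors are raised for empty fields and for ambiguous fields where a second
   component reaches 80% of the largest. The thresholded mask boundary sits
   on the *outer* flank of the membrane tube — roughly 1.2 × the effective
   tube σ outside the centerline — which is why the next step exists.
3. **Ridge refinement.** Each boundary point is moved along its local normal
   to the sub-pixel intensity maximum (quadratic fit around the sampled
   peak, search window ±1 µm). On noiseless synthetic renders this brings
   boundary error from several pixels down to ≲0.2 px.
4. **Resampling and correspondence.** The contour is resampled to N points
   (default 200) equally spaced in arc length, counterclockwise, with point
   0 placed where the contour crosses the angle-0 ray from the polygon
   centroid. Correspondence across frames is by this anchored index, not by
   mechanical boundary tracking; it assumes a near-stationary cell and is
   checked by rejecting centroid jumps above 25% of the mean radius.
5. **Curvature.** Coordinates are smoothed along the contour with a periodic
   Gaussian of scale σ_s (default 2 points), then differentiated with
   periodic central differences: κ = (x′y″ − y′x″)/(x′² + y′²)^{3/2}.
   Counterclockwise orientation makes convex cortex positive and ingressions
   negative. Accuracy at the defaults: ≤0.25% error on a circle (r = 10 µm,
   N = 200), ≤1% on the discrete turning number ∮κ ds = 2π, ≤2% at the
   high-curvature vertices of a 25 × 15 µm ellipse.

The curvature estimator replaces a boundary-dynamics ImageJ plugin used in
the original workflow whose internal estimator is unspecified; the furrow
statistic downstream depends only on the sign and temporal-variance pattern
of κ, which any consistent estimator preserves.

## The furrow statistic

Over an analysis window (default: all frames; the standard window is the
360 s before the end of meiosis I), each membrane point gets the temporal
mean μ_i and sample SD σ_i of its curvature. A point *qualifies* when

    μ_i < 0   and   σ_i ≥ threshold(σ_1 … σ_N)

and a furrow is a maximal circular run of qualifying points containing at
least two of them, where runs separated by exactly one non-qualifying point
are merged (repeatedly, to closure — the membrane is a ring, so runs and
merges wrap across the index origin).

**Threshold reading.** The defining phrase — an SD "at least two standard
deviations above the average standard deviation" — admits two readings:

- `twice_mean` (default): σ_i ≥ 2·mean(σ), and
- `above_spread`: σ_i ≥ mean(σ) + 2·SD(σ).

The statistically conventional `above_spread` reading fails structurally on
exactly the data this statistic is for. With a quiet baseline (non-furrowing
cortex has near-zero curvature SD), the per-point SDs form a sparse spike
mixture; as more furrows appear, both mean(σ) and SD(σ) grow with the spike
mass and the threshold converges to the spike height itself. In synthetic
recovery experiments it saturates around 4–5 detectable furrows regardless
of how many exist (errors up to 3 at K = 6), which would make the count
useless for the heavily furrowing phenotypes it is meant to separate. The
`twice_mean` reading recovers K exactly in 100% of 350 default-world runs
(K ∈ 0…6 × 50 seeds) and is therefore the default; `above_spread` remains
available via `sd_rule=` for comparability.

Counts can optionally exclude an angular sector (e.g. the spindle-associated
cortex); this is off by default since the original counts' handling of the
spindle region is not documented.

## Fluorescence metrics

- `total_spindle_intensity` = (mean grey(spindle ROI) / mean grey(cytoplasm
  ROI)) × spindle ROI area in pixels. ROIs are inputs (drawn by the analyst
  or emitted by the generator); the cytoplasm ROI must avoid confounding
  signal. The ratio form makes the metric invariant to global illumination
  scale.
- `ratio_series` reports the per-frame spindle-to-cytoplasm mean-grey ratio
  on the t = 0 convention.
- `patch_area_fraction` computes one threshold from the pooled histogram of
  all frames in the analysis window (default −360…0 s) — the "stack
  histogram" convention — using Otsu (between-class variance maximization)
  or Li (minimum cross-entropy), with dark background semantics: foreground
  is strictly greater than the threshold. Both thresholds are computed by
  exhaustive search over histogram cuts with ties broken toward the lowest
  cut; Li's fixed-point iteration is not used because the exhaustive
  minimizer reaches the same optimum without a convergence parameter (on
  plateaus of the objective — empty histogram gaps — any cut classifies
  identically; tests compare classifications against scikit-image).
  Histograms use native 8-bit bins for 8-bit data and 256 equal bins over
  the data range otherwise.
- Polygon ROI membership is pixel-center-in-polygon by the even-odd crossing
  rule with half-open edges — deterministic, including centers exactly on an
  edge.

## Group statistics

One-way ANOVA (classical SS decomposition, F with (k−1, N−k) df), two-tailed
variance F-tests (larger variance on top, p = min(1, 2 × upper tail)), and
two-tailed t-tests gated by the F-test at α = 0.05 (configurable): pooled
variance when the F-test does not reject, Welch–Satterthwaite otherwise.
Counts are treated as continuous, no multiple-testing correction by default
(a Bonferroni option exists) — both matching the original reporting style.
Degenerate zero-variance cases are reported as t = 0, p = 1 with a flag
rather than NaN. Under the null (normal, n = 10 per group, 10,000 fixed-seed
simulations) the gated test rejects at 4.65% for nominal 5%.

## The synthetic world

The generator emulates the acquisition the analysis assumes: an ellipse
cross-section with semi-axes a = 25, b = 15 µm at 0.1 µm/px, 37 frames at
10 s (the 360 s furrowing window), two channels, 1 µm z-spacing when z > 1.

Furrows are radial Gaussian indentations:

    r(θ, t) = r_ellipse(θ) − Σ_j d_j · env_j(t) · exp(−Δθ_j² / 2w_j²)

with depth d = 2 µm, a ramp/plateau/ramp temporal envelope, and per-frame
depth jitter `clip(g(t) + η·ξ_t, 0, ∞)` with η = 0.3 — the jitter elevates
curvature SD only at furrow sites, which is the signature the statistic
detects. Two choices matter and were made on realism grounds:

- **Furrow width is physical, not angular** (default arc-length σ = 1.5 µm,
  ≈3.5 µm FWHM, matching the few-µm ingressions seen in this system). A
  fixed angular width would make furrows on the far cortex (larger radius)
  physically wider and 2–3× weaker in curvature — an artifact of the
  parameterization.
- **Contour points are equal-arc-length samples** (dense radial model, then
  the same arc-length resampler the imaging pipeline uses), so index-space
  smoothing is uniform in physical length. Equal-angle sampling made the
  σ_s smoothing span 0.9–1.6 µm depending on position and spread furrow
  signatures ~2×.

Furrow positions are drawn with disjoint supports (circular gaps ≥ 6w) via a
Dirichlet gap construction unless overlap is explicitly allowed.

Rendering: the membrane is a Gaussian tube (σ_psf default 0.2 µm; the
diffraction limit of the emulated 1.4 NA objective is ≈0.1 µm, and tests of
boundary accuracy use that value) along the contour polyline plus a diffuse
cytoplasm fill; the chromatin channel holds a spindle blob and chromosome
puncta near the cortex; z-planes replicate the central plane with Gaussian
attenuation; noise is Poisson (counts = Poisson(gain × intensity)) followed
by Gaussian read noise (SD 10). The patchy-cortex generator produces disk
patches with per-frame turnover on a dark background, with the exact
noiseless-mask area fraction as ground truth.

**What green tests do and do not establish.** The synthetic world has a
stationary cell, isotropic Gaussian optics, no photobleaching, no neighboring
cells or gonad signal, furrows with disjoint supports and a shared temporal
envelope, and noise that is exactly Poisson + Gaussian. Passing tests
establish that the estimators and the counting rule are internally correct
and recover known truth under those assumptions — not that the pipeline
handles drifting cells, overlapping or migrating furrows, or the manual
judgment embedded in the original ROI drawing.

## Numerical details and degenerate inputs

- Sums/projections accumulate in widened dtypes (int64/float64); sum
  projections may exceed the source bit depth by design.
- Spindle-plane selection is the max-total-intensity contiguous window in z,
  ties to the lowest index — an automated stand-in for a manual choice, with
  an explicit override.
- Resampling anchors at the centroid-ray crossing; exact idempotence holds
  for contours commensurately sampled (e.g. regular polygons); generic
  polylines re-anchor to ~10⁻⁵ µm.
- All-equal σ profiles qualify on the SD criterion alone (threshold
  comparisons use ≥), so a noise-free static cortex with μ < 0 regions is
  handled deterministically.
- A single all-qualifying ring counts as one furrow; rings with fewer than
  two points cannot furrow.
- Curvature needs N ≥ 5; contours need N ≥ 16; windows need ≥ 2 frames;
  degenerate zero-perimeter contours and border-touching masks raise.

## Known limitations

- Angle-bin correspondence assumes a near-stationary, star-shaped-ish cell;
  strongly migrating or strongly non-convex cells would need boundary
  tracking.
- The furrow count has no sub-frame temporal resolution: a site that furrows
  twice within the window counts once.
- The 3-D structure is mocked (attenuated replication of the central plane);
  volumetric contractile-ring geometry is out of scope.
- Mask-level areas carry a positive bias of roughly half the membrane tube
  width; boundary-accurate quantities should use the ridge-refined contour.
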