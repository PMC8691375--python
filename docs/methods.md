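# Methods

This note records how `aaamorph` measures aneurysm geometry, how the
synthetic cohorts are constructed, and the numerical and design choices
behind both. All distances are millimetres; masks are boolean voxel
grids in a fixed anatomical index order (axis 0 axial/cranio-caudal,
axis 1 anteroposterior, axis 2 lateral), with strictly positive per-axis
spacing. NIfTI images are reoriented to this convention on read, so the
anteroposterior measurements are taken in a well-defined frame.

## Geometric features

**Maximal anteroposterior diameter.** For each axial slice containing
foreground the AP extent is `(max AP index − min AP index + 1) × AP
spacing`; the maximum over slices is the APD. The `+1` measures to the
outer voxel edges, so a filled box is measured exactly and a voxelized
ball is overestimated by at most one voxel. The phrase "maximum distance
between two points on the boundary" admits a second reading — the
maximum pairwise in-slice distance — which is available as
`mode="pairwise"` for sensitivity analysis; the default follows the
measure's name (an *anteroposterior* diameter) and is exact on box
phantoms.

**Undulation index.** `UI = 1 − V/V_CH` with `V` the foreground voxel
count times the voxel volume and `V_CH` the volume of the convex hull of
the *corner points* of the foreground voxels (equivalently, of the
boundary voxels — interior corners cannot be hull vertices). Both terms
measure the same outer voxel boundary, so any solid convex voxel set
(e.g. a cuboid) scores exactly 0 with no clamping involved; the result
is nevertheless clamped to [0, 1) as a float-safety net. The choice has
a known cost: the staircase surface of a voxelized *curved* solid is
genuinely non-convex, so smooth round shapes acquire a small positive UI
that scales with the voxel size (measured: ≈ 0.07 for a 25 mm-radius
ball at 1 mm spacing, halving as the spacing halves). Comparisons
against analytic UI values are therefore made at 0.5 mm spacing, where
the discretization bias is within ±0.02 for dumbbell-class shapes.

**Centerline and minimum radius of curvature.** The mask is thinned to
a one-voxel skeleton (topology-preserving 3D thinning); skeleton voxels
form a 26-connectivity graph with Euclidean edge weights, and the
longest geodesic between skeleton endpoints is kept — the infra-renal
segment is unbranched, so shorter spurs are thinning artifacts. The path
is fitted with a least-squares cubic b-spline parameterized by
normalized arclength with **fixed interior knots every 25 mm** of path
length, then evaluated at as many equally spaced parameter values as the
mask spans axial slices. Fixed sparse knots act as a low-pass filter
with a known cutoff: the spline can follow clinically relevant bends
(radii of tens of mm) while rejecting voxel-scale zigzag. A smoothing-
factor spline (FITPACK choosing its own knots) was tried first and
rejected: its fitted curvature oscillates, and since min RC takes a
minimum, the oscillation's worst point dominates (validation errors up
to −80% on lobulated bent tubes).

RC of a triplet is the circumradius `R = abc / 4A`; triplets whose
triangle area falls below 10⁻⁹ mm² are treated as collinear and return
an infinite sentinel. `min_radius_of_curvature` scans triplets
`(i − s, i, i + s)`; its own defaults are the literal adjacent scan
(stride 1, no exclusions), which is what the brute-force oracle tests
check. The *pipeline* default used by `extract_all_features` is
different, and deliberately so: at one point per ~1 mm axial slice the
sagitta of an adjacent triplet on a 40 mm-radius bend is ≈ 0.003 mm —
far below the voxel quantization noise of any skeleton — so adjacent
triplets cannot identify clinical radii. The pipeline therefore uses
chords spanning a fifth of the centerline (`stride = n_points // 5`) and
ignores the outer 10% of triplets at each curve end, where thinning
artifacts concentrate. Validated on voxelized bent tubes (tube radius
10–12 mm, bend radius 30–80 mm, 1 mm spacing) the worst error of the
pipeline configuration is −12%; straight tubes return the infinite
sentinel. Before model fitting the sentinel is capped at 10,000 mm so
design matrices stay finite — far above the clinical range (tens of mm),
so the cap is inert for realistic vessels.

## Growth and cohort rules

Annualized growth is `(APD_fu − APD_bl) / (days / 365)`; negative growth
(measurement noise can produce apparent shrinkage) is allowed and falls
in the *slow* category. Categories: slow < 2.5, some 2.5–5.0 (closed
interval: exactly 2.5 and exactly 5.0 are "some"), fast > 5.0 mm/yr.
Serial pairs with fewer than 244 days (8 × 30.5, the "more than 8
months" inclusion rule) between scans are excluded by the cohort filter;
the threshold is configurable.

## Prediction models

Cohorts are split reproducibly into training and testing sets (default
100/92 out of 192). On the training set a regularization strength is
selected by k-fold cross-validation (default 10 folds) over the grid
{0, 0.01, 0.1, 1, 10}: ridge penalty for the linear model (0 = ordinary
least squares), inverse-C for the multinomial logistic model. Features
are z-scored *inside* each fold on that fold's training statistics to
avoid leakage; folds are stratified by growth category for the logistic
model, since three classes on ~100 rows otherwise make empty-class folds
likely. Validation loss is RMSE (linear) or mean multinomial deviance
(logistic); ties break toward the weaker penalty, so a noise-free cohort
is fit by plain least squares and recovers generating coefficients to
machine precision. The final model is refit on the full training set and
coefficients are mapped back to the original units. For linear fits,
classical OLS standard errors on the original scale are attached; when a
small ridge penalty was selected these are approximate, but the shrinkage
at the grid's scale is well below one standard error at n = 100.

ROC analysis binarizes one-vs-rest on the fitted class probability
(slow vs not-slow, fast vs not-fast) and uses the trapezoidal area; the
tie-corrected Mann-Whitney statistic `U/(n₁n₀)` is implemented
separately as a cross-check and agrees to 10⁻¹². AUROC differences
between two models on a shared test set are tested by paired bootstrap
over test rows (default 2000 resamples; resamples that lose a class are
redrawn), two-sided.

## Synthetic phantoms and cohorts

Phantoms are tubes of varying radius swept along a straight or
circular-arc axis and voxelized by center inclusion (voxel center inside
the solid ⇒ foreground), which is unbiased at fixed spacing; measured
voxel volumes agree with the analytic solid volume within 3% at 1 mm
spacing for radii ≥ 10 mm. The radius profile is
`r(s) = base + bulge(s) + lobulation(s)` with a Gaussian bulge (focal
sac) and a `sin²` lobulation (multi-lobed sac, raising UI monotonically
with amplitude). Straight phantoms are placed with the axis through
exact voxel centers so thinning recovers the axis without parity
artifacts. A dumbbell phantom (two spheres joined by a thin coaxial
cylinder) carries exact solid-geometry truth for both its union volume
and its convex hull (a capsule), giving an analytic UI oracle. Grids are
capped (default 192 per side; the default bank stays within ~128³) and
generation fails loudly if a solid does not fit.

The default cohort bank contains 14 phantoms: four tube radii
(18–36 mm, i.e. 40–90 mm diameters) × three bend radii (60, 80, 105 mm)
with relative lobulation amplitudes (0, 0.15, 0.3 of the radius)
assigned in a Latin-square pattern, plus two focally bulged sacs, all
70 mm long at 1.5 mm spacing. Two deliberate choices decorrelate the
three extracted features across the bank: lobulation is *relative* to
the radius (otherwise UI is confounded with size), and arc angles are
kept below ~1.2 rad (otherwise the bow-shaped hull gap ties UI to the
bend and the clinical correlation pattern becomes unreachable).

Each synthetic patient draws a phantom from the bank (features are
extracted once per phantom and memoized), a follow-up interval, and an
annual growth `β₀ + β·(APD, UI, RCᶜᵃᵖ) + 𝒩(0, σ)`; the follow-up APD is
back-computed through the growth identity, so the cohort is exactly
self-consistent. Defaults: intercept 1.24, β = (0.033 per mm, 12.5 per
unit UI, −0.028 per mm RC), σ = 1.5 mm/yr — solved once against the
bank's empirical feature covariance so that the marginal feature–growth
rank correlations reproduce the clinical pattern (≈ +0.22, +0.39, −0.47
for APD, UI, RC) with growth centered near 3.7 mm/yr. Intervals are
log-normal with median 2.0 yr and log-SD 0.97 (interquartile range
≈ 1.0–3.7 yr), redrawn until ≥ 244 days. All randomness flows from a
single integer seed; repeat runs are byte-identical.

What the generator does *not* emulate: intraluminal thrombus and lumen
texture, branch vessels, CT intensity and partial-volume effects,
registration error between serial scans, and real segmentation noise.
Passing tests therefore demonstrate that the measurement and modelling
machinery is correct on shapes whose truth is known — not that the
clinical effect sizes would be recovered from real CT data.

## Test problem sizes

The suite exercises the geometry on phantoms of ~40–130 mm extent at
0.5–1.5 mm spacing; model-recovery checks use 200 replicate cohorts of
n = 100 at σ = 1.5 mm/yr (coefficient coverage within 3 SE) and 50
replicate cohorts of n = 192 with a 100/92 split (feature-set ordering
of AUROC and RMSE). These sizes give stable Monte-Carlo estimates while
keeping the full suite around a minute on a laptop-class machine.

## Known limitations

- UI carries a positive voxelization bias for smooth curved shapes
  (see above); compare UI across scans at matched resolution only.
- The min-RC estimator reports the curvature of a low-pass-filtered
  centerline; radii far above ~100 mm are reported but not meaningful,
  and radii of very short vessels (< 3 axial slices) are not defined.
- The paired-bootstrap ROC comparison assumes exchangeable test rows;
  it does not model uncertainty in the training stage.
- Growth in the simulated cohorts is feature-linked by construction;
  the models' clinical validity cannot be established synthetically.
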