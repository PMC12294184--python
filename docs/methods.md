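# Methods

## Measurement model

The package measures five parameters on annotated crops of unerupted lower
second permanent molar buds from panoramic radiographs. All geometry is
defined on explicit landmark annotations (0-based pixel coordinates, x
rightward, y downward, points at pixel centers); there is no automatic
segmentation or landmark detection, matching how such measurements are made
interactively with an angle/line tool.

**Reference rectangle.** The bud's longitudinal axis (two annotated points)
gives the vertical direction; the rectangle's vertical sides are the lines
through the mesial and distal CEJ points parallel to that direction. EA and
DA are the acute angles (degrees, range [0, 90]) between the vertical
direction and the straight two-point enamel-surface / DEJ segments of each
side. Angles are unsigned: the clinically meaningful quantity is how far
the segment tilts off the rectangle side, not in which direction. Both
operators are exactly rotation-invariant because only direction vectors
enter.

**Densitometry.** The mineralization profile is a straight line of length
twice the local enamel thickness, centred on the annotated DEJ anchor at
half crown height and directed perpendicular to the bud axis, from dentine
to enamel. Grey values are sampled by bilinear interpolation at 0.5 px
spacing (a sub-pixel approximation of a pixelwise plot profile). EDMR =
mean(middle third of the enamel half) / mean(middle third of the dentine
half). Numerical conventions, fixed so the quantity is testable: the
middle third of a half of length n is its central ⌊n/3⌋ samples (at least
one); an odd-length profile drops the central (DEJ) sample before
splitting; a zero dentine mean raises an undefined-ratio error. EDMR is
invariant under any positive rescaling of the grey values, which makes it
comparable across devices with arbitrary grey calibration.

**Aggregation.** Per patient, each parameter pools every available
(side × tooth) value — up to 4 angle/EDMR values and 2 W/H values — into a
mean and *sample* SD (ddof = 1; SD = 0 for a single value). Missing
entries are excluded and counted, never imputed as zero. Pooling all
available values (rather than averaging per tooth first) is one of two
defensible conventions; the per-parameter count in the output makes the
choice auditable.

## Classification thresholds

Cut-offs are the medians of the per-patient means over a healthy control
group, reported with 25th/75th percentiles (linear-interpolation
estimator; the quartile rule is a documented choice since several exist).
Published control values are EA 14.63° (q1 12.5, q3 17), DA 7.22°
(5.5, 8.75) and EDMR 1.06 (1.025, 1.125), available as `PAPER_DEFAULT`.
Flags use strict inequalities (`value < cut`); a value exactly at the cut
is unflagged. Hypoplasia is reported as two independent flags (by EA and
by DA) rather than a combined verdict, because genotypes exist in which
the DEJ inclination is distinctly reduced while the enamel surface is
normal. A missing parameter yields an undetermined (`None`) flag.

## Phantom generator

The generator renders the exact geometry the operators assume: an
isosceles trapezoidal crown, widest at the occlusal edge, symmetric about
a vertical axis, with straight enamel surfaces inclined at the true EA and
straight DEJs at the true DA, a dentine core, and a uniform background.
`enamel_thickness_px` is the horizontal enamel thickness at half crown
height, so the profile line of length 2t centred on the DEJ ends exactly
on the enamel surface. Rendering assigns each pixel the grey level of the
region containing its center (no anti-aliasing, so noiseless interior
pixels equal the spec's grey levels exactly), then applies Gaussian blur,
additive Gaussian noise, clipping and quantization to 8- or 16-bit.
Rendering is a pure function of the spec including its seed. Specs whose
enamel band would self-intersect, whose surfaces would cross above the
CEJ, or whose dentine core would vanish are rejected as geometry errors.

Cohort sampling draws each spec field from a truncated normal. The control
distributions put the EA/DA/EDMR medians at the published control cut-offs
(14.63°, 7.22°, 1.06) with SD = IQR/1.349 from the published quartiles
(3.34°, 2.41°, 0.074); the affected group shifts DA strongly (mean 4.5°),
EDMR moderately (0.95) and EA barely (13.5°), each with 1.5× SD,
reproducing the qualitative pattern that DA and EDMR separate
variant-positive patients while EA alone does not. Grey levels are fixed
at dentine 120 with enamel = 120 × EDMR on the 8-bit scale (EDMR is a
ratio, so the absolute scale is immaterial). Two known artefacts of the
sampler: 8-bit quantization perturbs the realized EDMR by at most ~0.004,
and geometric-feasibility rejection truncates the joint EA/DA distribution
slightly (large EA with small DA thins the enamel band below the crown),
which biases the realized EA median a few tenths of a degree below its
nominal value in derived-threshold simulations.

What the phantoms deliberately do **not** emulate: anatomical cusps,
panoramic projection distortion and jaw curvature, superimposed
structures, device-specific noise spectra, and observer landmarking error.
Passing the phantom suite therefore demonstrates that the operators are
correct implementations of their geometric/densitometric definitions, not
that the end-to-end method is robust on clinical images.

## Statistics

- **ICC** — computed from the two-way ANOVA mean squares; default form is
  two-way random effects, absolute agreement, single measure (ICC(A,1)),
  with one-way (ICC1) and consistency (ICC3) forms selectable. A matrix
  with zero total variance returns NaN (agreement undefined). The
  implementation is cross-checked against pingouin in the test suite.
- **PERMANOVA** — one-way, on Euclidean distances of z-scored features
  (population SD). Pseudo-F comes from the distance decomposition
  SS_total = Σ_{i<j} d²/n, SS_within = Σ_g Σ_{i<j∈g} d²/n_g. When the
  number of distinct label assignments is ≤ n_perm the null is enumerated
  exhaustively and p = #{F_perm ≥ F_obs}/N with the identity included;
  otherwise n_perm seeded random permutations are drawn and
  p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm), so p is never exactly zero.
  Default n_perm = 9999.
- **Mann–Whitney** — exact for combined n ≤ 16: the full null distribution
  of U is enumerated over all C(n, nx) assignments of the pooled mid-ranks,
  and the two-sided p sums both tails of the (symmetric) distribution.
  Larger samples delegate to the tie-corrected normal approximation with
  continuity correction.
- **FDR** — Benjamini–Hochberg step-up (via statsmodels). Note BH is not
  idempotent in general; the guaranteed properties are monotonicity in the
  order statistics, capping at 1, and never falling below the raw p.
- **DBSCAN** — sklearn on z-scored features, min_pts = 4 by default and
  eps from the maximum-curvature point of the sorted k-distance curve when
  not given; validated against a direct neighborhood-expansion
  implementation in the tests.
- **Prediction harness** — per iteration: down-sample the majority class
  to balance, stratified 70/30 train/test split, fit, score held-out ROC
  AUC. Defaults: 50 iterations, random forest with 500 trees, logistic
  regression unpenalized on standardized features. Importances are RF
  impurity importances and absolute standardized LR coefficients; the
  report carries the full per-iteration AUC and importance distributions,
  the median AUC and its across-iteration IQR. All resampling derives from
  a single seed. With a *fixed* random labeling of ~48 subjects the
  dataset-level AUC has substantial variance of its own (observed
  per-labeling medians 0.31–0.67 under the null), so the chance-level
  check pools iterations over several independent label shuffles, whose
  pooled median sits at 0.5.

## Problem sizes

The validation suite uses 100 random noiseless phantoms for operator
recovery (tolerances: angles ±0.5°, EDMR ±0.01, W/H ±1 px — generous
covers for rasterization and quantization), exhaustive-oracle agreement on
statistics instances with ≤ 8 subjects, 1000 null simulations (16 subjects,
299 permutations each) for PERMANOVA type-I calibration, 10⁴ × 2 ratings
matrices for the ICC variance-ratio check, and 24 + 24 synthetic cohorts
with 50-iteration harness runs — sizes chosen to mirror the study design
(24 patients vs 24 controls) while keeping every check cheap enough to run
routinely. The acceptance script averages derived thresholds over 20
replicate rendered control cohorts of 24.

## Limitations

- Landmark quality bounds everything: the operators propagate annotation
  error directly, and the phantoms do not model it.
- The variant table is consumed as printed evidence; ACMG criteria,
  population frequencies and segregation are annotations, not recomputed.
- Synthetic-cohort statistics (AUCs, p-values) characterize the harness on
  the generator's distributions, not the clinical cohort, whose raw data
  are not redistributable.
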