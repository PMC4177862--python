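# Methods

This note documents the models and procedures `ccmorph` implements, the
defaults and why they were chosen, what the synthetic data does and does
not emulate, and the numerical conventions that make results
bit-reproducible.

## Shape: minimum rectangle and bending angle

The bending angle summarizes callosal arching with a single number: the
vertex angle of the isosceles triangle that shares the base *b* and height
*h* of the minimum rectangle circumscribing the ROI, θ = 2·arctan(b/2h)
(degrees, reported to one decimal). It is scale-invariant — only the b/h
ratio matters — and strictly monotone in each of b and h, so "smaller θ ⇔
more convex arch" is unambiguous.

Two rectangle modes are exposed because "minimum rectangle" is ambiguous on
aligned images:

* `axis_aligned` (default): the tight axis-aligned bounds. Appropriate when
  masks come from images already realigned along the anterior–posterior
  commissure line, where the callosal base is horizontal by construction.
* `min_area`: the true minimum-area rectangle of the foreground convex
  hull. The search is edge-aligned, which is exact (a minimum-area
  enclosing rectangle always has a side collinear with a hull edge); the
  test suite verifies it against a brute-force 0.1° rotation sweep.

A length read off a pixel grid is ambiguous by one pixel, so both
conventions are selectable: `pixel_extent` (default) bounds whole pixel
squares — a filled run of n pixels has length n·spacing, consistent with
pixel-count areas — while `pixel_center` bounds pixel centers. Masks whose
foreground spans a single row or column have no 2-D rectangle and are
rejected ("zero-extent rectangle").

## Five-region subdivision

Four cuts perpendicular to the rectangle's long side at cumulative
fractions 0.33, 0.50, 0.67, 0.80 of the base length, measured from the
anterior end, produce the anterior third, anterior mid-body, posterior
mid-body, isthmus and splenium. The anterior third is deliberately kept
whole (rostrum/genu/rostral body cannot be separated by straight cuts).

Membership is a half-open pixel-center rule — a pixel belongs to slab k
when its center's projection onto the base axis lies in [start_k, end_k),
last slab closed — chosen so that the partition is exact (every foreground
pixel receives exactly one label) and boundary pixels are assigned
deterministically. Slab widths consequently differ from the exact
fractional widths by less than one pixel.

Image handedness is never guessed: the caller declares where the anterior
end lies along the column axis (`anterior_direction` ∈ {`+col`, `-col`}).
Flipping the image and the declaration together mirrors the labels, which
the tests assert.

## Synthetic cohorts

The generator provides the study conditions for all parameter-recovery
testing, at two levels:

**Single masks** (`make_cc_shape`). An arch whose bounding rectangle and
per-slab areas are controlled exactly: the lower envelope follows a
half-ellipse spanning the base (zero at the end columns, height minus the
local thickness at the apex), and each proportional slab is thickened
vertically by its own constant thickness. Per-column pixel counts are
distributed by cumulative rounding, so each planted slab area is met to
within half a pixel (tolerance asserted: ≤ 2 % or ≤ 4 mm²). A single
left-to-right pass shifts (never resizes) column bands so the mask stays
4-connected. Thickness is purely piecewise-constant — no tapering at slab
joins — because any taper would trade exact per-slab area bookkeeping for
cosmetic smoothness, and the acceptance surface needs the former.
Feasibility requires each slab thickness ≤ height/2 and ≥ one pixel;
infeasible demands raise a named error.

**Cohorts** (`sample_mask_cohort`). Per subject, the five region areas and
the bending angle are drawn from group-specific normals truncated at 3 SD
(a deliberate deviation from the pure normal model, to keep geometry sane),
the angle is inverted to a base/height ratio (base fixed at 100 mm), and a
mask is built; draws that remain infeasible after 100 attempts raise an
error naming the offending parameter. A single master seed is fanned out
one `SeedSequence` child per subject, so any subject can be regenerated in
isolation and cohorts are bit-identical under one seed.

The shipped defaults are the emulated CB/NC study conditions: n = 28 per
group (16 M / 12 F), ages 19–63, splenium 260.84 ± 41.7 (NC) vs
225.64 ± 31.7 mm² (CB), posterior mid-body 89.64 ± 16.51 vs
107.26 ± 21.67 mm², isthmus 64.16 ± 10.31 vs 79.4 ± 16.66 mm², bending
angle 113.4 ± 5.7° vs 109.6 ± 4.9°, with sex-specific isthmus cells
87.24 ± 18.81 / 68.95 ± 11.83 / 63.49 ± 10.05 / 65.06 ± 11.04 mm². The two
anterior regions have no documented group difference, so both groups share
one realistic value there (anterior third 330 ± 45, anterior mid-body
95 ± 15 mm²), fixed once and not tuned. Three acquisition sites are
emulated with an 8 : 11 : 9 allocation.

`simulate_area_table` bypasses imaging entirely (independent untruncated
normal draws per region, uniform ages, linear scale 1) and is what the
statistical calibration and F-recovery simulations use.

What the synthetic data does **not** emulate: anatomically realistic
callosal contours (fornix ambiguity, rostrum curvature), intensity data,
partial-volume effects, within-subject correlation between region areas,
or site/scanner effects beyond labels. Passing recovery tests therefore
demonstrates correctness of the measurement machinery, not segmentation
robustness on real MRI.

## Template construction and area measurement

Registration is a demons-style matcher: sum-of-squared-differences forces
(`-diff·∇I / (|∇I|² + diff²)`, bounded steps) with fluid-like smoothing of
each update (σ = 1 px) and diffusion regularization of the accumulated
field (Gaussian smoothing, σ configurable), run coarse-to-fine over an
image pyramid (default levels 4/2/1 with 100/80/60 iterations). Binary
masks are Gaussian-smoothed (σ = 1 px) into soft-edged images before
matching, since binary SSD has flat gradients. Registration is fully
deterministic; stochastic initialization is forbidden by contract.

The template loop starts from the voxel-wise mean of the (integer-shift
centred) binary masks and iterates: register every subject to the smoothed
current template; warp the *binary* subjects into template space; average
them into a temporary template; apply the inverse of the average
deformation (fixed-point inversion of the mean displacement field) to the
temporary template. The default schedule runs 4 iterations with field
regularization σ halving 8 → 4 → 2 → 1 px, so early iterations absorb
gross shape differences and later ones refine. Divergence — the mean deformation
magnitude growing by more than half its previous value in two consecutive
iterations (mean |u| legitimately creeps upward as the schedule loosens,
so slow growth is not flagged) — aborts with diagnostics. After the loop, subjects are re-registered
to the final template; on a symmetric two-subject translation case the
voxel-wise average of these final fields has mean magnitude ≈ 0.18 px over
the template foreground (the unbiasedness figure is quoted over the
foreground because background displacements carry no data term).

Fields map **template coordinates to subject coordinates**, so the Jacobian
determinant det(I + ∇u) (central differences, one-sided at borders) is the
local subject/template area ratio, and summing it over a template-space
label times the pixel area gives that subject's region area — one expert
labelling of the template serves the whole cohort. The template is
labelled by thresholding at 0.5 and applying the same rectangle +
subdivision used for single subjects. Non-positive determinants are never
clamped; they are counted and reported per subject.

Brain-size normalization is abstracted to a per-subject scalar
`linear_scale` (native → stereotaxic): input masks are treated as already
size-normalized, integration yields stereotaxic areas, and native areas
divide by `linear_scale²`. The synthetic generator sets the scale to 1, so
the two spaces coincide there — flagged rather than silently assumed.

**Accuracy envelope (measured on a 12-subject default-settings cohort).**
Whole-CC Jacobian-integrated area agrees with each subject's own
pixel-count area to < 1 %; the splenium (broad, bounded by the callosal
tip) recovers its planted area to < 3 % per subject. The narrow interior
slabs (anterior mid-body, isthmus: 13–17 % of the base) can deviate by up
to ~25 % for individual subjects: their boundaries are proportional cuts
inside uniform foreground, not image features, so their correspondence is
determined by the regularizer — the same limitation any intensity-driven
registration has inside homogeneous white matter. Group *means* are far
tighter since these deviations are unbiased leakage between neighbours.
Tighter regularization schedules were evaluated and worsened interior
slabs (boundary overfitting), so the defaults stand.

## Group statistics

The linear model is `area ~ group (+ sex + group:sex) + age`, fitted by
OLS; effect F values are Type III, computed as full-vs-reduced model
comparisons under sum-to-zero factor coding (equivalent to Type III in
this design, and cross-checked in the tests against
`statsmodels.stats.anova.anova_lm(typ=3)`). Sum-to-zero coding is required
for the 2 × 2 interaction F to reproduce the cell-mean contrast
(m₁₁ − m₁₂) − (m₂₁ − m₂₂) in unbalanced designs. Age enters linearly and
uncentred; centring does not change any F (asserted by test). No
Welch-type corrections anywhere — the ANCOVA is classical. With n = 56 and
one factor plus age, the residual df is 53 (two factors with interaction:
51); the df arithmetic asserted in tests is this model's own.

The five sub-region group tests pass a fixed Bonferroni gate: significant
iff p ≤ 0.01 (0.05/5, applied inclusively at the boundary). Scheffé
post-hoc contrasts among the four group-by-sex cells use the interaction
ANCOVA's error variance and residual df: for a pairwise contrast,
F_c = diff² / (MSE·(1/nᵢ + 1/nⱼ)) and p = P(F_{k−1,dfe} ≥ F_c/(k−1)) with
k = 4 cells; this is conservative relative to the unadjusted test for
every contrast (asserted). Cell means are age-adjusted to the grand mean
age before contrasting. Site differences are checked by one-way ANOVA on
native-space total CC area (never stereotaxic, which would mask scanner
differences in size normalization).

Under null simulation the group ANCOVA's type-I error is within 1.5
percentage points of nominal over 2000 replicates, and null site-ANOVA
p-values are uniform (KS-tested).

A statistical caveat worth stating: the *replicate average* of an F
statistic simulated at fixed population means exceeds the F one would
compute at those means, because E[F(1, ν, λ)] = (1+λ)·ν/(ν−2) while the
"plug-in" F equals λ. For strong effects (λ ≈ 12) the inflation is ~12 %;
for the isthmus interaction (λ ≈ 7.2) it is ~20 %. The acceptance
simulations report the replicate mean as specified, so the interaction
recovery sits systematically above the published single-sample value; this
is a property of the estimator, not a model error.

## Pipeline and reproducibility

`run_pipeline` sequences cohort → template → labelling → Jacobian areas →
statistics from one YAML config, logging each stage with its settings and
wall time, and writes a provenance JSON (config + SHA-256 hash, seed,
package and numpy versions, template history). All randomness flows from
the single master seed through per-subject `SeedSequence` children;
registration is deterministic; CSVs are bit-identical across re-runs of
the same config (asserted by test). Default problem sizes used in the test
and acceptance suites — 100 × 35 px masks, 6–12-subject cohorts, 2000
statistical replicates — were chosen as the smallest sizes at which the
geometric tolerances above are meaningful.

## Known limitations

* 2-D only; no 3-D template, no left–right symmetrization, no raw-MRI
  preprocessing (masks are the input contract).
* Interior slab boundaries are regularization-determined (see accuracy
  envelope above).
* The demons matcher is not guaranteed diffeomorphic; folding is reported,
  not prevented.
* The scalar `linear_scale` stands in for a full affine stereotaxic
  normalization.
* Scheffé p-values use the classical homoscedastic formula; heteroscedastic
  cells are not corrected (by design, matching the classical battery).
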