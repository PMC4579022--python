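# Methods

This note records the model, the numerical choices, and the defaults behind
`dfmorph`, and what validation on synthetic phantoms does and does not show.

## Synthetic phantom cohorts

The phantom emulates the coronal tissues whose deformation discriminates AD
from normal controls (NC): a bright cortical ring (intensity 0.9), mid-gray
interior tissue (0.55), a dark butterfly-shaped lateral-ventricle region
(≈0.05) built from two overlapping ellipses, and two hippocampus-like blobs
(0.35) inferior-lateral to the ventricle. All edges are logistic-softened
over ≈1 px so image gradients are informative for registration. Geometry
defaults scale with the image size (cortical outer radius 0.40·size,
thickness 0.08·size, ventricle half-width 0.10·size, hippocampal radius
0.045·size).

NC subjects are jittered renderings: each geometric parameter receives
multiplicative Gaussian jitter (SD = `subject_variation`, default 3%) plus a
small random centre offset, shared across the subject's slice stack. AD
subjects are the *same* clean renderings warped by a known parametric
deformation and only then given additive Gaussian intensity noise
(`noise_sd`, default 0.02 on a [0, 1] scale), so the ground-truth field
exactly explains the AD/NC difference up to noise.

The deformation is built in backward-warping convention (the field maps
output coordinates into the source image):

- **Ventricle enlargement** (`ventricle_scale` s ≥ 1): inside the enlarged
  ventricle footprint, the source point is pulled toward the ventricle
  centre by 1/s with a Gaussian-tapered profile outside, so the dark region's
  linear size grows by s and its area by s².
- **Cortical shrinkage** (`cortex_scale` ≤ 1): a radial outward-sampling
  Gaussian bump centred on the ring compresses the cortex toward its
  shrunken radius.

The summed field is Gaussian-smoothed (σ = 1.5 px) so it is smooth at the
scale the estimator assumes, and sub-1e-6 px vectors are snapped to zero so
the affected mask is exactly the support of the nonzero vectors. Along the
coronal index the effect is weighted by a raised cosine that is exactly zero
on the outer quarter of slices — pathology is confined to central slices, as
in stacks through the ventricles — and overall brain size is mildly modulated
to mimic an ellipsoidal head.

Default cohort imbalance follows roughly 1 AD : 3 NC so the behaviour of
precision versus specificity under imbalance is visible in the metrics.

What the phantom does **not** emulate: real anatomical shape variability,
bias fields and acquisition artefacts, partial-volume effects, 3D geometry
(each slice is deformed independently in-plane), or any calibrated effect
size — the enlargement/shrinkage factors are free parameters, not fitted to
a clinical population. Passing on phantoms validates the algorithmic chain
(field recovery, feature discrimination, protocol correctness), not clinical
performance.

## Key-slice selection

Inter-class variance v(k) = ‖μ_A(k) − μ_N(k)‖² uses plain arithmetic group
means of gray values, no intensity normalisation. A slice is kept iff
v(k) > max(v)/2 **and** it falls on the undersampling grid
((k − anchor) mod step = 0); the two conditions are a conjunction, and the
anchor (default 0) makes the grid usable on short toy stacks. The threshold
is relative, so global intensity rescaling (which scales every v(k) by c²)
leaves the selection unchanged. An empty selection is legal and returned
as-is; the pipeline then falls back to the single argmax slice with a
warning.

## Displacement-field estimation

Level-set motion: the moving image morphs along its own gradient, driven by
the intensity residual. The discrete scheme is explicit Euler,

    V ← V + Δt · G_σ ∗ [ (I₂ − I₁(V)) ∇I₁(V) / (|∇I₁(V)| + ε) ] ,

with these choices:

| parameter | default | meaning |
|---|---|---|
| `time_step` Δt | 0.4 | Euler step (px per unit intensity residual) |
| `smooth_sigma` σ | 1.5 px | Gaussian regularisation of each update |
| `grad_eps` ε | 10⁻³ × intensity range | stabiliser of the normalised gradient |
| `stop_tol` | 10⁻⁴ | relative residual-change convergence tolerance |
| `max_iters` | 200 | iteration cap |

Design notes:

- The **update increment** is smoothed, not the accumulated field
  (fluid-like rather than diffusion-like regularisation). Smoothing the full
  field every iteration keeps contracting it and caps the recoverable
  amplitude well below the true warp; smoothing the increment regularises
  each force field while letting displacement accumulate. With the smooth
  ground-truth fields used throughout, recovered mean endpoint error is
  ≈0.3–0.5 px for warps of ≈3–5 px maximum magnitude.
- Gradients are central differences on the currently warped image with
  edge replication (`numpy.gradient`); warping is backward bilinear with
  boundary-value extension, so a zero field reproduces the input exactly.
- **Monotone residual control**: a step that would increase ‖I₂ − I₁(V)‖ is
  rejected and the time step halved; after 8 consecutive rejections the
  iteration stops (and raises a convergence error if the residual never
  improved at all). The logged residual sequence is therefore non-increasing
  by construction.
- Because intensity matching is the only driving force, the estimator is
  subject to the aperture problem: in flat regions and along level sets the
  true displacement component is unobservable and the estimate relaxes to
  the smallest field consistent with the intensities. Tests that quantify
  translation recovery therefore use patterns with gradient support
  everywhere (gratings) or restrict the error to the deformed support.
- Rigid pre-alignment (rotation + translation, Powell from the identity on
  mean squared difference, bounded to ±30° and ±15 px) precedes non-rigid
  estimation; the identity is kept whenever the optimiser cannot improve it,
  so registration never increases the MSE.

Polar conversion: magnitude = √(u² + w²); direction = atan2(w, u) wrapped to
[0, 2π), with direction ≡ 0 wherever magnitude is exactly zero so features
are deterministic. `u` is the horizontal (column) component and `w` the
vertical (row) component, 0-based pixel indexing.

## Features and PCA

For each subject and key slice, the template — by default the per-slice mean
of the NC group, optionally a named subject — is rigidly aligned to the
subject slice, the field is estimated with the template as moving image and
the subject as reference, and the polar channels are flattened magnitude
first, then direction, concatenated across key slices. A fixed template
makes rows comparable across subjects; a subject identical to the template
yields an exactly zero row. Magnitude and direction are concatenated by
default; either channel can be used alone. Direction values are treated as
plain features in radians, without circular statistics.

PCA is computed by SVD of the column-centred matrix; the retained count is
the smallest one whose cumulative explained variance reaches the requested
fraction (default 0.95; 1.0 keeps all numerically nonzero directions).
Zero-variance input degenerates to one arbitrary unit component with a
warning. Inside cross-validation the PCA is fitted on training rows only and
applied to validation rows.

## Classifiers

All three classifiers are linear; kernels are out of scope.

**GEPSVM.** Plane i solves min U≠0 (UᵀPU)/(UᵀQU) with
P = [X₁ −o]ᵀ[X₁ −o] + tI and Q = [X₂ −o]ᵀ[X₂ −o] (roles swapped for the
second plane). The Tikhonov factor defaults to t = 10⁻⁴. The pencil is
solved by the QZ algorithm, which tolerates a singular denominator
(null-space directions surface as infinite eigenvalues and are skipped);
candidate eigenpairs are accepted only when the residual ‖PU − λQU‖ is below
10⁻⁶ of the matrix scale, and a pencil with no clean finite eigenpair raises
with the suggestion to increase t. Both eigen-residuals are stored on the
model.

**TSVM.** Each of the two QPs is solved through its box-constrained dual:
with H = [X_own o], G = [X_other o] and ridge 10⁻⁸·tr(HᵀH) on HᵀH, the dual
min ½αᵀG(HᵀH)⁻¹Gᵀα − oᵀα over 0 ≤ α ≤ c is minimised by L-BFGS-B with tight
tolerances, and u = −(HᵀH)⁻¹Gᵀα. Duality gap, primal feasibility and
complementary slackness are recorded per QP (≈10⁻¹⁰ or better on the tested
problems). Penalties default to c₁ = c₂ = 1; note they are scale-coupled —
the proximal term is quadratic in the data scale while the margin constraint
is fixed at 1 — so data living at unit scale (such as the cross-planes
benchmark) wants small penalties (0.01 there), while PCA scores at larger
scale work with c = 1.

**Decision rule.** Neither formulation prescribes one; both models assign
the class of the nearer plane under the norm-normalised distance
|wᵢᵀx ∓ bᵢ|/‖wᵢ‖, with ties broken to class 1 (AD), biasing toward
sensitivity. Swapping the class arguments swaps the planes and inverts every
prediction; rescaling all features rescales the planes but changes no
prediction.

**Baseline SVM.** The soft-margin linear SVM delegates to libsvm (sklearn
`SVC`, default tol 10⁻³ with an iteration cap); its primal objective
½‖w‖² + C·Σ hinge is exposed for verification against an independent QP
solve. The degenerate all-identical-features case returns the
majority-class constant predictor.

Hyperparameters default to t = 10⁻⁴, c₁ = c₂ = 1, C = 1 and are passed
through `run_cv`'s classifier spec; no tuning is performed by default —
a grid search inside training folds can be layered on, but at phantom scale
it changes none of the tested properties while multiplying the CV cost.

## Evaluation protocol

Repeated stratified K-fold CV (defaults K = 10): per repetition a fresh
seeded split; per fold, PCA + classifier fitted on training rows only;
out-of-fold predictions assembled into one full-cohort confusion table per
repetition (not per-fold averaging), from which accuracy, sensitivity,
specificity and precision are computed; mean ± SD across repetitions.
Stratification is the default because at ≈1:3.5 imbalance plain random folds
frequently contain no AD subject; a class with fewer than K members falls
back to unstratified folds with a warning. Ratios with zero denominators are
reported as NaN with a warning rather than silently clamped. AD (label 1)
is the positive class throughout.

## Region detection

R = {(x, y) : |V(x, y)| > T}, strict inequality, T = 5 px by default (chosen
empirically; lowering it admits more noise, raising it drops genuine small
deformations). Detection between a control and an AD subject runs rigid
alignment + field estimation per key slice and thresholds each field. The
raw rule can fire slightly outside the brain where the estimator follows
background distortion; an optional brain-mask intersection suppresses this
and is off by default. No anatomical labelling is attempted.

## Problem sizes used in the tests and the acceptance script

Phantom validation uses 64-px slices, 16-subject cohorts (4 AD / 12 NC) with
9-slice stacks, 10 field-recovery pairs, and 5 CV repetitions; the
permutation-null check uses the 28/98 cohort size with 5 repetitions. These
sizes exercise every code path with comfortable statistical margins while
keeping the full validation in the tens of seconds on one CPU; all of them
are function arguments, so larger studies are a parameter change.

## Known limitations

- The field estimator recovers only intensity-observable displacement
  (aperture problem); direction features are meaningful mainly where the
  magnitude is appreciable.
- 2D in-plane fields only; no 3D extension, no Talairach-space
  normalisation or brain masking (inputs are assumed rigidly pre-normalised
  upstream; only 2D rigid pre-alignment is provided).
- Phantom effect sizes are free parameters — perfect phantom accuracy under
  a strong effect demonstrates pipeline correctness, not expected clinical
  accuracy.
- TSVM penalties are data-scale dependent (see above); there is no automatic
  rescaling.
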