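# dfmorph

Displacement-field morphometry for detecting Alzheimer's disease (AD) from
structural brain MR images.

Atrophy in AD is not a single number: the lateral ventricles enlarge while
the cerebral cortex and hippocampus shrink, and these changes deform the
whole coronal cross-section of the brain. `dfmorph` turns that deformation
itself into the classification feature. A normal template slice is non-rigidly
registered to each subject's slice, and the resulting per-pixel displacement
field — how far and in which direction every template pixel must move to
match the subject — is fed to a classifier. The same field, thresholded by
magnitude, marks the image regions that drive the discrimination.

The pipeline:

1. **Key-slice selection.** For coronal index *k*, the inter-class variance
   is v(k) = ‖μ_A(k) − μ_N(k)‖², the squared ℓ₂-norm of the difference
   between the AD-group and control-group mean slices. Slices with
   v(k) > max(v)/2, thinned by an undersampling step, are kept.
2. **Displacement-field estimation.** After rigid pre-alignment, the moving
   slice I₁ evolves by level-set motion along its own intensity gradient,
   dV/dt = (I₂ − I₁(V)) ∇I₁(V)/|∇I₁(V)|, until it matches the reference I₂.
   The Cartesian field (u, w) is converted to polar magnitude/direction
   channels, which form the feature vector (reduced by PCA inside each
   cross-validation fold).
3. **Classification.** Three linear classifiers: a soft-margin SVM baseline
   and two non-parallel-plane variants — GEPSVM, which finds each plane as
   the generalized eigenvector of the smallest eigenvalue of a
   Tikhonov-regularized Rayleigh quotient, and the twin SVM (TSVM), which
   solves two SVM-like quadratic programs, one plane proximal to each class.
4. **Region detection.** R = {(x, y) : |V(x, y)| > T} with T = 5 px by
   default: pixels whose displacement magnitude exceeds the threshold are
   reported as AD-related region candidates.
5. **Evaluation.** Repeated stratified 10-fold cross-validation with
   out-of-fold assembly; accuracy, sensitivity, specificity and precision
   reported as mean ± SD over repetitions (AD counts as positive).

Because clinical volumes cannot ship with a package, `dfmorph` includes a
synthetic phantom module that generates coronal brain-slice cohorts — bright
cortical ring, dark butterfly ventricle, hippocampal blobs — where AD-like
subjects are produced by a *known* smooth deformation. Every stage can
therefore be validated against ground truth.

## Worked example

```python
import numpy as np
from dfmorph import (PhantomSpec, make_cohort, compute_icv_curve,
                     select_key_slices, build_features, run_cv)

spec = PhantomSpec(image_size=64, seed=5, ventricle_scale=1.5,
                   cortex_scale=0.95, noise_sd=0.02)
cohort, truths = make_cohort(n_ad=4, n_nc=12, spec=spec, n_slices=9)

curve = compute_icv_curve(cohort)
key = select_key_slices(curve, undersampling=2)
print("ICV curve:", np.round(curve.v, 2))
print("key slices:", key.indices, " threshold:", round(key.threshold, 2))

features = build_features(cohort, key)
report = run_cv(features.X, features.y, "tsvm", K=10, repeats=5, seed=3)
for name, stats in report.summary().items():
    print(f"{name}: {stats['mean']:.4f} +- {stats['sd']:.4f}")
```

Output:

```
ICV curve: [ 2.03  2.27  2.51 21.82 88.82 21.84  2.47  2.34  2.05]
key slices: [4]  threshold: 44.41
accuracy: 1.0000 +- 0.0000
sensitivity: 1.0000 +- 0.0000
specificity: 1.0000 +- 0.0000
precision: 1.0000 +- 0.0000
```

The AD effect is confined to the central slices, so the inter-class variance
peaks at the middle coronal index (88.82) and only slice 4 clears half the
maximum (44.41) on the undersampling grid. With a strong ventricle
enlargement (×1.5) the twin SVM separates the 4 AD from the 12 control
phantoms perfectly in every cross-validation repetition; shrinking
`ventricle_scale` toward 1 degrades the accuracy toward the majority-class
fraction.

The same stages are available from the shell:

```
dfmorph phantom --n-ad 4 --n-nc 12 --seed 5 --out cohort/
dfmorph keyslices --manifest cohort/manifest.csv --step 2 --out key.json
dfmorph features --manifest cohort/manifest.csv --keyslices key.json --out feats.npz
dfmorph evaluate --features feats.npz --classifier tsvm --out report.json
dfmorph regions --manifest cohort/manifest.csv --nc NC000 --ad AD000 \
    --keyslices key.json --t 5 --out regions.csv
```

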