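"""Shared fixtures: phantom cohorts and displacement-recovery runs are
expensive, so they are session-scoped and reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from dfmorph.dispfield import LevelSetParams, estimate_displacement, warp
from dfmorph.phantom import PhantomSpec, make_cohort


@pytest.fixture(scope="session")
def strong_cohort():
    """16-subject cohort (4 AD / 12 NC) with a strong, centrally confined
    AD effect (ventricle enlargement x1.5, cortical shrinkage x0.95)."""
    spec = PhantomSpec(image_size=64, seed=5, ventricle_scale=1.5,
                       cortex_scale=0.95, noise_sd=0.02)
    cohort, gts = make_cohort(4, 12, spec, n_slices=9)
    return cohort, gts


@pytest.fixture(scope="session")
def zero_effect_cohort():
    """Same cohort layout but with unit scales: AD and NC differ only by
    subject jitter and noise."""
    spec = PhantomSpec(image_size=64, seed=11, ventricle_scale=1.0,
                       cortex_scale=1.0, noise_sd=0.02)
    cohort, gts = make_cohort(4, 12, spec, n_slices=9)
    return cohort, gts


@pytest.fixture(scope="session")
def recovery_pairs():
    """Ten matched moving/reference pairs with known smooth ground-truth
    fields (max magnitude <= 5 px), plus the estimated fields.

    Each pair warps a clean NC phantom slice by its subject's ground-truth
    deformation and estimates the field back with default parameters.
    """
    results = []
    for seed in range(10):
        spec = PhantomSpec(image_size=64, seed=seed, ventricle_scale=1.3,
                           cortex_scale=0.97, noise_sd=0.01)
        cohort, gts = make_cohort(1, 1, spec, n_slices=5)
        nc = cohort.group(0)[0]
        k = 2  # central slice carries the full effect
        gt = gts[0].fields[k]
        mask = gts[0].affected_masks[k]
        moving = nc.slices[k]
        reference = warp(moving, gt)
        est = estimate_displacement(moving, reference, LevelSetParams())
        epe = np.hypot(est.u - gt.u, est.w - gt.w)
        log = est.iteration_log
        results.append({
            "gt": gt, "mask": mask, "estimate": est,
            "mean_epe": float(epe[mask].mean()),
            "mse_reduction": 1.0 - (log[-1] / log[0]) ** 2,
            "log": log,
        })
    return results


@pytest.fixture(scope="session")
def cross_planes():
    """The cross-planes (XOR-like) dataset: class 1 near y = x, class 2 near
    y = -x, +-0.05 uniform noise, 40 points each, fixed seed."""
    rng = np.random.default_rng(42)
    t1 = rng.uniform(-1, 1, 40)
    t2 = rng.uniform(-1, 1, 40)
    X1 = np.c_[t1, t1 + rng.uniform(-0.05, 0.05, 40)]
    X2 = np.c_[t2, -t2 + rng.uniform(-0.05, 0.05, 40)]
    return X1, X2
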