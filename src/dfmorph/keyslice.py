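"""Key-slice selection by inter-class variance (ICV).

For each coronal index ``k`` the ICV is the squared l2-norm of the difference
between the AD-group and NC-group mean slices,

    v(k) = || mu_A(k) - mu_N(k) ||^2 ,

and the key slices are those whose ICV exceeds half the maximum, thinned by an
undersampling factor (every ``step``-th slice).  Both conditions must hold
(conjunction): a slice is kept iff v(k) > max(v)/2 and (k - anchor) % step == 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import CohortDataset

__all__ = ["ICVCurve", "KeySliceSet", "inter_class_variance", "compute_icv_curve",
           "select_key_slices"]


@dataclass
class ICVCurve:
    """Inter-class variance per coronal slice, with the group mean slices."""

    v: np.ndarray          # (n_slices,)
    mu_A: np.ndarray       # (n_slices, H, W) AD-group mean
    mu_N: np.ndarray       # (n_slices, H, W) NC-group mean


@dataclass
class KeySliceSet:
    indices: list[int]     # strictly increasing selected coronal indices
    threshold: float       # half of max ICV
    undersampling: int


def _group_means(cohort: CohortDataset, k: int) -> tuple[np.ndarray, np.ndarray]:
    ad = cohort.slice_stack(k, label=1)
    nc = cohort.slice_stack(k, label=0)
    return ad.mean(axis=0), nc.mean(axis=0)


def inter_class_variance(cohort: CohortDataset, k: int) -> float:
    """ICV of coronal slice ``k``: squared l2-norm of the group-mean difference."""
    if not cohort.group(1) or not cohort.group(0):
        raise ValueError("ICV requires at least one AD and one NC subject")
    mu_a, mu_n = _group_means(cohort, k)
    return float(np.sum((mu_a - mu_n) ** 2))


def compute_icv_curve(cohort: CohortDataset) -> ICVCurve:
    """Evaluate the ICV at every coronal index of the cohort."""
    if not cohort.group(1) or not cohort.group(0):
        raise ValueError("ICV requires at least one AD and one NC subject")
    mu_a = np.stack([_group_means(cohort, k)[0] for k in range(cohort.n_slices)])
    mu_n = np.stack([_group_means(cohort, k)[1] for k in range(cohort.n_slices)])
    v = np.sum((mu_a - mu_n) ** 2, axis=(1, 2))
    return ICVCurve(v=v, mu_A=mu_a, mu_N=mu_n)


def select_key_slices(curve: ICVCurve | np.ndarray, undersampling: int = 10,
                      anchor: int = 0) -> KeySliceSet:
    """Select slices with v(k) > max(v)/2 that fall on the undersampling grid.

    ``anchor`` offsets the grid (kept slices satisfy (k - anchor) % step == 0),
    useful for short toy stacks.  The strict inequality means an all-zero
    curve selects nothing.  An empty selection is returned as-is; callers
    should warn.
    """
    v = curve.v if isinstance(curve, ICVCurve) else np.asarray(curve, dtype=float)
    if v.size == 0:
        raise ValueError("ICV curve is empty")
    if undersampling < 1:
        raise ValueError("undersampling step must be >= 1")
    threshold = float(v.max()) / 2.0
    indices = [int(k) for k in range(v.size)
               if v[k] > threshold and (k - anchor) % undersampling == 0]
    return KeySliceSet(indices=indices, threshold=threshold,
                       undersampling=undersampling)
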