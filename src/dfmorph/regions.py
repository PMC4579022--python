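"""AD-related region detection by displacement-magnitude thresholding.

A pixel belongs to the detected region set iff the polar magnitude of the
displacement field strictly exceeds the threshold T:

    R = {(x, y) : |V(x, y)| > T} ,

with T = 5 px by default.  Region detection between a normal and an AD subject
runs rigid alignment + level-set displacement-field estimation per key slice
and thresholds each field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dispfield import (DisplacementField, LevelSetParams, estimate_displacement,
                        rigid_register)
from .keyslice import KeySliceSet
from .phantom import Subject

__all__ = ["RegionSet", "detect_regions", "region_mask", "run_region_detection",
           "DEFAULT_THRESHOLD"]

DEFAULT_THRESHOLD = 5.0


@dataclass
class RegionSet:
    """Pixels whose displacement magnitude exceeds ``threshold_T``.

    Points are (x, y) = (column, row) pairs, matching the horizontal/vertical
    component convention of the displacement field.
    """

    points: set[tuple[int, int]]
    threshold_T: float
    source_slice: int = -1

    def __len__(self) -> int:
        return len(self.points)


def detect_regions(field: DisplacementField, T: float = DEFAULT_THRESHOLD,
                   source_slice: int = -1,
                   brain_mask: np.ndarray | None = None) -> RegionSet:
    """Return exactly the pixels with magnitude strictly greater than ``T``.

    ``brain_mask`` optionally suppresses background pixels (the raw rule can
    fire slightly outside the brain where the estimator follows background
    distortion); it is off by default.
    """
    if T <= 0:
        raise ValueError("threshold T must be positive")
    mag = field.magnitude()
    keep = mag > T
    if brain_mask is not None:
        keep &= np.asarray(brain_mask, dtype=bool)
    rr, cc = np.nonzero(keep)
    points = {(int(x), int(y)) for y, x in zip(rr, cc)}
    return RegionSet(points=points, threshold_T=float(T), source_slice=source_slice)


def region_mask(regions: RegionSet, shape: tuple[int, int]) -> np.ndarray:
    """Binary image with 1 at region points; sum equals the number of points."""
    mask = np.zeros(shape, dtype=np.uint8)
    for x, y in regions.points:
        if not (0 <= y < shape[0] and 0 <= x < shape[1]):
            raise ValueError(f"point (x={x}, y={y}) outside shape {shape}")
        mask[y, x] = 1
    return mask


def run_region_detection(nc_subject: Subject, ad_subject: Subject,
                         key_slices: KeySliceSet, T: float = DEFAULT_THRESHOLD,
                         params: LevelSetParams | None = None) -> list[RegionSet]:
    """Detect AD-related regions between one NC and one AD subject.

    Per key slice: rigidly align the NC slice (moving) to the AD slice
    (reference), estimate the displacement field, and threshold its magnitude.
    Convergence failures of the estimator propagate.
    """
    out = []
    for k in key_slices.indices:
        _, registered = rigid_register(nc_subject.slices[k], ad_subject.slices[k])
        fld = estimate_displacement(registered, ad_subject.slices[k], params)
        out.append(detect_regions(fld, T=T, source_slice=k))
    return out
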