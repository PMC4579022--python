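"""Per-subject displacement-field features over key slices, reduced by PCA.

For every subject and every key slice, a fixed template (the NC mean slice by
default) is rigidly aligned to the subject slice, the level-set displacement
field is estimated with the template as moving image and the subject as
reference, and the field's polar magnitude and direction channels are
flattened and concatenated across slices.  A fixed template makes rows
comparable across subjects.  The resulting matrix is reduced by PCA to the
smallest number of components reaching a requested explained-variance
fraction; in cross-validation the PCA is always fitted on training rows only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dispfield import LevelSetParams, estimate_displacement, rigid_register, to_polar
from .keyslice import KeySliceSet
from .phantom import CohortDataset

__all__ = ["FeatureMatrix", "PCAModel", "build_features", "fit_pca", "transform"]


@dataclass
class FeatureMatrix:
    """n_subjects x n_features matrix with labels and a column-block layout.

    ``layout`` records, per block, (slice index, channel name, column start,
    column stop); before reduction n_features = n_keyslices x 2 x pixels.
    """

    X: np.ndarray
    y: np.ndarray
    layout: list[tuple[int, str, int, int]] = field(default_factory=list)

    def column_info(self, j: int) -> tuple[int, str, int]:
        """(slice index, channel, pixel offset) of column ``j``."""
        for k, channel, start, stop in self.layout:
            if start <= j < stop:
                return k, channel, j - start
        raise IndexError(f"column {j} outside layout")


@dataclass
class PCAModel:
    mean: np.ndarray                      # feature-space mean
    components: np.ndarray                # (n_components, n_features) orthonormal rows
    explained_variance: np.ndarray        # eigenvalues of the covariance
    explained_variance_ratio: np.ndarray
    n_components: int


def build_features(cohort: CohortDataset, key_slices: KeySliceSet,
                   template: str = "mean-nc",
                   params: LevelSetParams | None = None,
                   channels: tuple[str, ...] = ("magnitude", "direction"),
                   rigid: bool = True) -> FeatureMatrix:
    """Build the per-subject polar displacement-field feature matrix.

    ``template`` is either ``"mean-nc"`` (per-slice arithmetic mean of the NC
    subjects) or a subject id.  For each subject and key slice the template
    slice is the moving image and the subject slice the reference, so feature
    vectors describe how the common template must deform to match each
    subject.  Channels are flattened magnitude-then-direction per slice and
    concatenated across slices; row order equals cohort order.
    """
    if not key_slices.indices:
        raise ValueError("key_slices is empty")
    bad = set(channels) - {"magnitude", "direction"}
    if bad:
        raise ValueError(f"unknown channels: {sorted(bad)}")

    if template == "mean-nc":
        nc = cohort.group(0)
        if not nc:
            raise ValueError("template 'mean-nc' requires NC subjects")
        template_slices = {k: np.mean([s.slices[k] for s in nc], axis=0)
                           for k in key_slices.indices}
    else:
        match = [s for s in cohort.subjects if s.subject_id == template]
        if not match:
            raise ValueError(f"template subject {template!r} not in cohort")
        template_slices = {k: match[0].slices[k] for k in key_slices.indices}

    rows = []
    layout: list[tuple[int, str, int, int]] = []
    for i, sub in enumerate(cohort.subjects):
        parts = []
        col = 0
        for k in key_slices.indices:
            tmpl = template_slices[k]
            subj = sub.slices[k]
            try:
                moving = tmpl
                if rigid:
                    _, registered = rigid_register(tmpl, subj)
                    moving = registered
                fld = estimate_displacement(moving, subj, params)
            except Exception as exc:
                raise RuntimeError(
                    f"displacement estimation failed for subject "
                    f"{sub.subject_id}, slice {k}") from exc
            pol = to_polar(fld)
            for channel in channels:
                vals = getattr(pol, channel).ravel()
                parts.append(vals)
                if i == 0:
                    layout.append((k, channel, col, col + vals.size))
                col += vals.size
        rows.append(np.concatenate(parts))
    X = np.vstack(rows)
    return FeatureMatrix(X=X, y=cohort.labels, layout=layout)


def fit_pca(X: np.ndarray, variance_fraction: float = 0.95) -> PCAModel:
    """PCA of the column-centred data, keeping the smallest component count
    whose cumulative explained variance reaches ``variance_fraction``.

    Components are the covariance eigenvectors ordered by decreasing
    eigenvalue (computed by SVD of the centred matrix).  Zero-variance input
    degenerates to a single arbitrary unit component with a warning.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("fit_pca requires at least 2 rows")
    if not (0 < variance_fraction <= 1):
        raise ValueError("variance_fraction must be in (0, 1]")
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    ev = s**2 / (X.shape[0] - 1)
    total = ev.sum()
    if total <= np.finfo(float).tiny * X.shape[1]:
        warnings.warn("zero-variance input to fit_pca; keeping 1 component")
        comp = np.zeros((1, X.shape[1]))
        comp[0, 0] = 1.0
        return PCAModel(mean=mean, components=comp,
                        explained_variance=np.zeros(1),
                        explained_variance_ratio=np.zeros(1), n_components=1)
    # drop numerically-zero directions so variance_fraction=1.0 keeps full rank only
    keep = ev > ev[0] * 1e-12
    ev, vt = ev[keep], vt[keep]
    ratio = ev / total
    n_comp = int(np.searchsorted(np.cumsum(ratio), variance_fraction - 1e-12) + 1)
    n_comp = min(n_comp, ev.size)
    return PCAModel(mean=mean, components=vt[:n_comp],
                    explained_variance=ev[:n_comp],
                    explained_variance_ratio=ratio[:n_comp], n_components=n_comp)


def transform(model: PCAModel, X: np.ndarray) -> np.ndarray:
    """Centered projection of rows onto the retained components."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.mean.size:
        raise ValueError(
            f"dimension mismatch: {X.shape[1]} columns vs model {model.mean.size}")
    return (X - model.mean) @ model.components.T
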