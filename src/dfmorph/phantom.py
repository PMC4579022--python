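"""Synthetic coronal brain-slice phantoms with known ground-truth deformations.

Each phantom slice emulates the tissues whose deformation is indicative of
Alzheimer's disease on a coronal view: a bright cortical ring, a dark
butterfly-shaped lateral-ventricle region at the centre, and two
hippocampus-like blobs below the ventricle.  Normal-control (NC) subjects are
jittered copies of the base geometry; AD subjects are NC phantoms warped by a
known smooth deformation field realising parametric ventricle enlargement
(``ventricle_scale``) and cortical shrinkage (``cortex_scale``), so every
downstream stage — slice selection, displacement-field estimation, region
detection, classification — can be validated against ground truth without any
external data.

The deformation is generated parametrically (radial expansion centred on the
ventricle, radial expansion localised at the cortical ring that compresses it
inward) and Gaussian-smoothed so it is diffeomorphic-like at phantom scale.
The AD effect varies across the coronal index with a raised-cosine profile
that is exactly zero on the outer quarter of slices, confining pathology to
central slices as in real coronal stacks through the ventricles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .dispfield import DisplacementField, SliceImage, warp

__all__ = [
    "PhantomSpec",
    "GroundTruthDeformation",
    "Subject",
    "CohortDataset",
    "make_phantom_slice",
    "make_cohort",
    "save_cohort",
    "load_cohort",
]

_EDGE = 1.0  # sigmoid edge softness, px


@dataclass
class PhantomSpec:
    """Geometry and effect parameters of the phantom cohort.

    All radii/widths are in pixels; ``None`` resolves to a fraction of
    ``image_size`` at construction.  ``ventricle_scale >= 1`` enlarges the
    ventricle (AD-like); ``cortex_scale <= 1`` shrinks the cortical ring.
    """

    image_size: int = 128
    cortex_outer_radius: float | None = None   # default 0.40 * image_size
    cortex_thickness: float | None = None      # default 0.08 * image_size
    ventricle_halfwidth: float | None = None   # default 0.10 * image_size
    hippocampus_radius: float | None = None    # default 0.045 * image_size
    ventricle_scale: float = 1.5
    cortex_scale: float = 0.95
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if self.cortex_outer_radius is None:
            self.cortex_outer_radius = 0.40 * self.image_size
        if self.cortex_thickness is None:
            self.cortex_thickness = 0.08 * self.image_size
        if self.ventricle_halfwidth is None:
            self.ventricle_halfwidth = 0.10 * self.image_size
        if self.hippocampus_radius is None:
            self.hippocampus_radius = 0.045 * self.image_size
        if self.ventricle_scale < 1:
            raise ValueError("ventricle_scale must be >= 1")
        if not (0 < self.cortex_scale <= 1):
            raise ValueError("cortex_scale must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name in ("cortex_outer_radius", "cortex_thickness",
                     "ventricle_halfwidth", "hippocampus_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class GroundTruthDeformation:
    """Known warp applied to an NC phantom stack to produce its AD counterpart.

    One field (and its support mask) per coronal slice; ``affected_mask`` is
    exactly the support of the nonzero field vectors.
    """

    subject_id: str
    fields: list[DisplacementField]
    affected_masks: list[np.ndarray]


@dataclass
class Subject:
    subject_id: str
    label: int            # 1 = AD, 0 = NC
    cdr: int              # clinical dementia rating: 1 -> AD, 0 -> NC
    slices: np.ndarray    # (n_slices, H, W) in [0, 1]
    age: float = 75.0
    sex: str = "F"

    def slice_image(self, k: int) -> SliceImage:
        return SliceImage(self.slices[k])


@dataclass
class CohortDataset:
    """Labelled subjects with coronal slice stacks."""

    subjects: list[Subject] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.subjects], dtype=int)

    @property
    def n_slices(self) -> int:
        return self.subjects[0].slices.shape[0] if self.subjects else 0

    def group(self, label: int) -> list[Subject]:
        return [s for s in self.subjects if s.label == label]

    def slice_stack(self, k: int, label: int | None = None) -> np.ndarray:
        """(n_subjects, H, W) array of slice k, optionally restricted to one class."""
        subs = self.subjects if label is None else self.group(label)
        return np.stack([s.slices[k] for s in subs])


# ---------------------------------------------------------------------------
# geometry rendering


def _smoothstep(x):
    # logistic edge: 0 -> 1 over a ~2*_EDGE px band
    return 1.0 / (1.0 + np.exp(-np.clip(x / _EDGE, -40, 40)))


def _ventricle_mask(rows, cols, centre, halfwidth, scale):
    """Soft butterfly mask: union of two ellipses, the whole shape scaled by
    ``scale`` about the centre so its area grows as scale**2."""
    yr = (rows - centre[0]) / scale
    xr = (cols - centre[1]) / scale
    sep = 0.55 * halfwidth   # lobe offset from midline
    ay, ax = 1.5 * halfwidth, 0.85 * halfwidth  # lobe semi-axes
    m = np.zeros_like(yr)
    for sign in (-1.0, 1.0):
        d = np.sqrt((yr / ay) ** 2 + ((xr - sign * sep) / ax) ** 2)
        m = np.maximum(m, _smoothstep((1.0 - d) * ax))
    return m


def _render_geometry(spec: PhantomSpec, centre, size) -> np.ndarray:
    """Noise-free phantom: cortex ring 0.9, interior 0.55, ventricle ~0.05,
    hippocampal blobs 0.35, background 0."""
    rows, cols = np.indices((size, size), dtype=float)
    r = np.hypot(rows - centre[0], cols - centre[1])

    r_out = spec.cortex_outer_radius * spec.cortex_scale
    r_in = r_out - spec.cortex_thickness
    brain = _smoothstep(r_out - r)
    interior = _smoothstep(r_in - r)
    img = 0.9 * (brain - interior) + 0.55 * interior

    vw = spec.ventricle_halfwidth
    vmask = _ventricle_mask(rows, cols, centre, vw, spec.ventricle_scale)
    img = img * (1.0 - 0.92 * vmask * interior)

    # hippocampus-like blobs, inferior-lateral to the ventricle
    hr = spec.hippocampus_radius
    for sign in (-1.0, 1.0):
        hc = (centre[0] + 2.1 * vw, centre[1] + sign * 1.9 * vw)
        d = np.hypot(rows - hc[0], cols - hc[1])
        blob = _smoothstep(hr - d) * interior
        img = img * (1.0 - blob) + 0.35 * blob
    return np.clip(img, 0.0, 1.0)


def make_phantom_slice(spec: PhantomSpec, subject_variation: float = 0.0,
                       rng: np.random.Generator | None = None) -> SliceImage:
    """Render one phantom slice in [0, 1].

    ``subject_variation`` is the fractional SD of multiplicative geometry
    jitter (plus a centre offset of the same scale in pixels x10); with
    ``subject_variation = 0`` and ``noise_sd = 0`` the image is a
    deterministic function of the geometry parameters.  Deterministic given
    ``spec.seed`` (a fresh generator is derived from it when ``rng`` is None).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    centre = np.array([(size - 1) / 2.0, (size - 1) / 2.0])
    jspec = spec
    if subject_variation > 0:
        jit = lambda v: float(v * (1.0 + subject_variation * rng.standard_normal()))  # noqa: E731
        jspec = replace(
            spec,
            cortex_outer_radius=jit(spec.cortex_outer_radius),
            cortex_thickness=jit(spec.cortex_thickness),
            ventricle_halfwidth=jit(spec.ventricle_halfwidth),
            hippocampus_radius=jit(spec.hippocampus_radius),
        )
        centre = centre + subject_variation * 10.0 * rng.standard_normal(2)
    img = _render_geometry(jspec, centre, size)
    if spec.noise_sd > 0:
        img = np.clip(img + rng.normal(0.0, spec.noise_sd, img.shape), 0.0, 1.0)
    return SliceImage(img)


# ---------------------------------------------------------------------------
# ground-truth deformation


def _ad_deformation(spec: PhantomSpec, centre, size, effect_weight: float,
                    smooth_sigma: float = 1.5) -> tuple[np.ndarray, np.ndarray]:
    """Backward field (u, w) warping an NC slice into its AD counterpart.

    Ventricle: for output points inside the enlarged ventricle footprint the
    source point is pulled toward the centre by 1/s, so the dark region grows
    to ``s`` times its linear size.  Cortex: a radial outward sampling bump
    localised at the ring compresses it toward ``cortex_scale``.  The summed
    field is Gaussian-smoothed and tiny values are snapped to exactly zero so
    the affected mask is the exact support of nonzero vectors.
    """
    rows, cols = np.indices((size, size), dtype=float)
    dy, dx = rows - centre[0], cols - centre[1]
    r = np.hypot(dy, dx)

    s_v = 1.0 + (spec.ventricle_scale - 1.0) * effect_weight
    s_c = 1.0 - (1.0 - spec.cortex_scale) * effect_weight

    u = np.zeros((size, size))
    w = np.zeros((size, size))

    if s_v > 1.0:
        r0 = 1.6 * spec.ventricle_halfwidth * s_v  # enlarged ventricle extent
        prof = np.where(r <= r0, 1.0, np.exp(-((r - r0) ** 2) / (2 * (0.45 * r0) ** 2)))
        scale = (1.0 / s_v - 1.0) * prof  # negative: sample toward centre
        u += scale * dx
        w += scale * dy

    if s_c < 1.0:
        r_ring = spec.cortex_outer_radius * (1.0 + s_c) / 2.0
        sig = 1.2 * spec.cortex_thickness
        bump = np.exp(-((r - r_ring) ** 2) / (2 * sig ** 2))
        scale = (1.0 / s_c - 1.0) * bump  # positive: sample outward
        u += scale * dx
        w += scale * dy

    u = ndimage.gaussian_filter(u, smooth_sigma)
    w = ndimage.gaussian_filter(w, smooth_sigma)
    mag = np.hypot(u, w)
    tiny = mag < 1e-6
    u[tiny] = 0.0
    w[tiny] = 0.0
    return u, w


def _slice_effect_profile(n_slices: int) -> np.ndarray:
    """Raised-cosine AD-effect weight across the coronal index, exactly zero
    on the outer quarter of slices."""
    if n_slices == 1:
        return np.ones(1)
    k = np.arange(n_slices)
    mid = (n_slices - 1) / 2.0
    span = n_slices / 4.0  # inner half carries the effect
    x = (k - mid) / (2.0 * span)
    wgt = np.where(np.abs(x) < 0.5, 0.5 * (1.0 + np.cos(2.0 * np.pi * x)), 0.0)
    return wgt


def _slice_geometry_profile(n_slices: int) -> np.ndarray:
    """Mild ellipsoid-like modulation of the overall brain size along the stack."""
    if n_slices == 1:
        return np.ones(1)
    k = np.arange(n_slices)
    mid = (n_slices - 1) / 2.0
    return 0.85 + 0.15 * np.cos(np.pi * (k - mid) / (n_slices - 1))


def make_cohort(n_ad: int, n_nc: int, spec: PhantomSpec | None = None,
                n_slices: int = 9, subject_variation: float = 0.03,
                ) -> tuple[CohortDataset, list[GroundTruthDeformation]]:
    """Generate a labelled phantom cohort plus per-AD-subject ground truth.

    NC subjects are jittered base phantoms rendered with unit scales; each AD
    subject is an NC phantom warped slice-by-slice by the known smooth
    deformation implementing ``ventricle_scale``/``cortex_scale`` (weighted
    along the coronal index by a centrally-confined profile), with intensity
    noise added after warping.  Labels: 1 = AD, 0 = NC.  Bit-identical given
    the same spec (seed included) and counts.
    """
    if n_ad < 1 or n_nc < 1:
        raise ValueError("n_ad and n_nc must be >= 1")
    if spec is None:
        spec = PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    geo = _slice_geometry_profile(n_slices)
    eff = _slice_effect_profile(n_slices)
    base = replace(spec, ventricle_scale=1.0, cortex_scale=1.0, noise_sd=0.0)

    def render_stack(sub_rng):
        """Noise-free NC stack with per-subject jitter shared across slices."""
        jit = 1.0 + subject_variation * sub_rng.standard_normal(4)
        centre0 = (np.array([(size - 1) / 2.0] * 2)
                   + subject_variation * 10.0 * sub_rng.standard_normal(2))
        stack = np.empty((n_slices, size, size))
        centres = []
        specs = []
        for k in range(n_slices):
            g = geo[k]
            sk = replace(
                base,
                cortex_outer_radius=float(spec.cortex_outer_radius * jit[0] * g),
                cortex_thickness=float(spec.cortex_thickness * jit[1] * g),
                ventricle_halfwidth=float(spec.ventricle_halfwidth * jit[2] * g),
                hippocampus_radius=float(spec.hippocampus_radius * jit[3] * g),
            )
            stack[k] = _render_geometry(sk, centre0, size)
            centres.append(centre0)
            specs.append(sk)
        return stack, centres, specs

    def add_noise(stack, sub_rng):
        if spec.noise_sd > 0:
            stack = np.clip(stack + sub_rng.normal(0.0, spec.noise_sd, stack.shape), 0, 1)
        return stack

    cohort = CohortDataset()
    ground_truth: list[GroundTruthDeformation] = []

    for i in range(n_ad):
        sid = f"AD{i:03d}"
        sub_rng = np.random.default_rng(rng.integers(2**31))
        stack, centres, specs = render_stack(sub_rng)
        fields, masks = [], []
        warped = np.empty_like(stack)
        for k in range(n_slices):
            # effect scales derive from the subject's own jittered geometry
            sk = replace(specs[k], ventricle_scale=spec.ventricle_scale,
                         cortex_scale=spec.cortex_scale)
            u, w = _ad_deformation(sk, centres[k], size, eff[k])
            fld = DisplacementField(u=u, w=w)
            warped[k] = warp(stack[k], fld)
            fields.append(fld)
            masks.append(fld.magnitude() > 0)
        warped = add_noise(warped, sub_rng)
        age = float(np.clip(60 + 15 * sub_rng.random(), 60, 96))
        sex = "F" if sub_rng.random() < 0.5 else "M"
        cohort.subjects.append(Subject(sid, 1, 1, warped, age, sex))
        ground_truth.append(GroundTruthDeformation(sid, fields, masks))

    for i in range(n_nc):
        sid = f"NC{i:03d}"
        sub_rng = np.random.default_rng(rng.integers(2**31))
        stack, _, _ = render_stack(sub_rng)
        stack = add_noise(stack, sub_rng)
        age = float(np.clip(60 + 15 * sub_rng.random(), 60, 96))
        sex = "F" if sub_rng.random() < 0.5 else "M"
        cohort.subjects.append(Subject(sid, 0, 0, stack, age, sex))

    return cohort, ground_truth


# ---------------------------------------------------------------------------
# cohort I/O (NIfTI volumes + CSV manifest)


def save_cohort(cohort: CohortDataset, outdir) -> str:
    """Write one NIfTI volume per subject plus ``manifest.csv``.

    Volumes are stored with the coronal index on axis 1, i.e. voxel array
    shape (H, n_slices, W) so that ``vol[:, k, :]`` is coronal slice k.
    Manifest columns: subject_id, path, label, cdr, age, sex.
    """
    import os

    import nibabel as nib
    import pandas as pd

    os.makedirs(outdir, exist_ok=True)
    records = []
    for sub in cohort.subjects:
        vol = np.transpose(sub.slices, (1, 0, 2))  # (H, n_slices, W)
        path = os.path.join(outdir, f"{sub.subject_id}.nii")
        nib.save(nib.Nifti1Image(vol.astype(np.float32), affine=np.eye(4)), path)
        records.append({"subject_id": sub.subject_id, "path": path,
                        "label": sub.label, "cdr": sub.cdr,
                        "age": sub.age, "sex": sub.sex})
    manifest = os.path.join(outdir, "manifest.csv")
    pd.DataFrame.from_records(records).to_csv(manifest, index=False)
    return manifest


def load_cohort(manifest_path, coronal_axis: int = 1) -> CohortDataset:
    """Load a cohort from a manifest CSV referencing NIfTI volumes.

    CDR values must be 0 or 1 (subjects with other or missing records are not
    accepted); labels derive from CDR (1 -> AD, 0 -> NC).
    """
    import nibabel as nib
    import pandas as pd

    df = pd.read_csv(manifest_path)
    required = {"subject_id", "path", "cdr"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    cohort = CohortDataset()
    for _, row in df.iterrows():
        cdr = row["cdr"]
        if pd.isna(cdr) or int(cdr) not in (0, 1):
            raise ValueError(
                f"subject {row['subject_id']}: CDR must be 0 or 1, got {cdr!r}")
        cdr = int(cdr)
        vol = np.asarray(nib.load(row["path"]).get_fdata(), dtype=float)
        slices = np.moveaxis(vol, coronal_axis, 0)
        cohort.subjects.append(Subject(
            subject_id=str(row["subject_id"]), label=cdr, cdr=cdr, slices=slices,
            age=float(row.get("age", np.nan)) if "age" in df.columns else np.nan,
            sex=str(row.get("sex", "")) if "sex" in df.columns else "",
        ))
    return cohort
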