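"""Non-rigid displacement-field estimation by level-set motion.

The moving slice :math:`I_1` is morphed iteratively along its own intensity
gradient, driven by the residual to a reference slice :math:`I_2`:

.. math::

    \\frac{dV}{dt} = (I_2 - I_1(V)) \\, \\frac{\\nabla I_1(V)}{|\\nabla I_1(V)|}

where :math:`V` is the displacement field and :math:`I_1(V)` the moving image
warped by :math:`V`.  The field is complex-valued in spirit: the real part is
the horizontal (column) component ``u`` and the imaginary part the vertical
(row) component ``w``.  After estimation the Cartesian field is converted to
polar magnitude/direction channels, which are the classifier inputs downstream.

Conventions
-----------
* 0-based pixel indices; ``u`` indexes columns, ``w`` indexes rows.
* Backward warping: ``warp(img, V)[r, c] = img[r + w[r, c], c + u[r, c]]``
  (bilinear, edge-replicated), i.e. the field maps reference-frame coordinates
  into the moving image.
* The discrete scheme is an explicit Euler iteration with the unit-normalised
  gradient stabilised by a small ``grad_eps`` and the updated field smoothed by
  a Gaussian each iteration (diffusion-like regularisation).  Steps that would
  increase the residual are rejected and retried with a halved time step, so
  the logged residual sequence is non-increasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

__all__ = [
    "SliceImage",
    "DisplacementField",
    "PolarField",
    "LevelSetParams",
    "RigidTransform",
    "ConvergenceError",
    "rigid_register",
    "estimate_displacement",
    "warp",
    "to_polar",
]


def _as_pixels(image) -> np.ndarray:
    """Accept a SliceImage or a bare 2D array; return float64 pixels."""
    pix = image.pixels if isinstance(image, SliceImage) else image
    pix = np.asarray(pix, dtype=float)
    if pix.ndim != 2:
        raise ValueError(f"expected a 2D slice, got shape {pix.shape}")
    return pix


@dataclass
class SliceImage:
    """A 2D grayscale coronal slice with pixel spacing in mm."""

    pixels: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("SliceImage requires a 2D array")
        if self.pixels.shape[0] < 8 or self.pixels.shape[1] < 8:
            raise ValueError("SliceImage must be at least 8x8 pixels")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("SliceImage pixels must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class DisplacementField:
    """Per-pixel 2-vector field: ``u`` horizontal (columns), ``w`` vertical (rows)."""

    u: np.ndarray
    w: np.ndarray
    iteration_log: list[float] = field(default_factory=list)

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if self.u.shape != self.w.shape:
            raise ValueError("u and w must have the same shape")
        if not (np.all(np.isfinite(self.u)) and np.all(np.isfinite(self.w))):
            raise ValueError("displacement components must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u, self.w)


@dataclass
class PolarField:
    """Polar encoding of a displacement field.

    ``magnitude`` is the Euclidean vector norm in pixels; ``direction`` is the
    angle of ``(u, w)`` in radians mapped to [0, 2*pi), forced to 0 wherever
    the magnitude is exactly zero.
    """

    magnitude: np.ndarray
    direction: np.ndarray


@dataclass
class LevelSetParams:
    """Iteration machinery for the level-set motion scheme.

    Parameters
    ----------
    time_step : explicit-Euler step (pixels per unit intensity residual).
    max_iters : iteration cap.
    smooth_sigma : Gaussian sigma (pixels) applied to the field each iteration.
    grad_eps : gradient-magnitude stabiliser as a fraction of the intensity
        range of the input pair.
    stop_tol : relative residual-change tolerance for convergence.
    divergence_limit : consecutive rejected steps after which iteration stops
        (with an error if no progress was ever made).
    """

    time_step: float = 0.4
    max_iters: int = 200
    smooth_sigma: float = 1.5
    grad_eps: float = 1e-3
    stop_tol: float = 1e-4
    divergence_limit: int = 8

    def __post_init__(self):
        if self.time_step <= 0 or self.smooth_sigma <= 0 or self.grad_eps <= 0:
            raise ValueError("time_step, smooth_sigma and grad_eps must be positive")
        if self.stop_tol <= 0:
            raise ValueError("stop_tol must be positive")
        if self.max_iters < 1:
            raise ValueError("max_iters must be at least 1")


@dataclass
class RigidTransform:
    """Rotation (radians, about the image centre) plus (row, col) translation."""

    angle: float
    shift: tuple[float, float]  # (row, col)

    @property
    def is_identity(self) -> bool:
        return self.angle == 0.0 and self.shift == (0.0, 0.0)


class ConvergenceError(RuntimeError):
    """Raised when the level-set iteration cannot reduce the residual at all."""

    def __init__(self, message: str, iteration_log: list[float]):
        super().__init__(message)
        self.iteration_log = iteration_log


# ---------------------------------------------------------------------------
# warping


def warp(image, dfield: DisplacementField):
    """Backward-map ``image`` through ``dfield`` with bilinear interpolation.

    Out-of-bounds samples take the nearest boundary value.  A zero field
    returns the input pixels exactly.  Returns the same kind of object it was
    given (SliceImage in, SliceImage out).
    """
    pix = _as_pixels(image)
    if dfield.shape != pix.shape:
        raise ValueError(f"field shape {dfield.shape} != image shape {pix.shape}")
    rows, cols = np.indices(pix.shape, dtype=float)
    out = ndimage.map_coordinates(
        pix, [rows + dfield.w, cols + dfield.u], order=1, mode="nearest"
    )
    if isinstance(image, SliceImage):
        return SliceImage(out, spacing=image.spacing)
    return out


# ---------------------------------------------------------------------------
# rigid pre-alignment


def _rigid_resample(pix: np.ndarray, angle: float, shift: tuple[float, float]) -> np.ndarray:
    """Sample ``pix`` at rotated+shifted coordinates (backward mapping)."""
    h, w = pix.shape
    cr, cc = (h - 1) / 2.0, (w - 1) / 2.0
    rows, cols = np.indices(pix.shape, dtype=float)
    dr, dc = rows - cr, cols - cc
    ca, sa = np.cos(angle), np.sin(angle)
    src_r = cr + ca * dr - sa * dc + shift[0]
    src_c = cc + sa * dr + ca * dc + shift[1]
    return ndimage.map_coordinates(pix, [src_r, src_c], order=1, mode="nearest")


def rigid_register(moving, reference):
    """Rigidly align ``moving`` to ``reference`` by minimising the MSE.

    A local optimiser (Powell) starts from the identity; if it cannot improve
    on the identity transform the identity is returned, so registration never
    increases the mean squared intensity difference.

    Returns
    -------
    (RigidTransform, registered image) — the registered image is the moving
    image resampled by the optimal transform.
    """
    mov = _as_pixels(moving)
    ref = _as_pixels(reference)
    if mov.shape != ref.shape:
        raise ValueError("moving and reference must share a shape")
    if not (np.all(np.isfinite(mov)) and np.all(np.isfinite(ref))):
        raise ValueError("images must be finite")

    def cost(p):
        return float(np.mean((_rigid_resample(mov, p[0], (p[1], p[2])) - ref) ** 2))

    identity_mse = float(np.mean((mov - ref) ** 2))
    res = optimize.minimize(
        cost,
        x0=np.zeros(3),
        method="Powell",
        bounds=[(-np.pi / 6, np.pi / 6), (-15.0, 15.0), (-15.0, 15.0)],
        options={"xtol": 1e-4, "ftol": 1e-8, "maxiter": 2000},
    )
    if res.fun < identity_mse:
        tf = RigidTransform(float(res.x[0]), (float(res.x[1]), float(res.x[2])))
        registered = _rigid_resample(mov, tf.angle, tf.shift)
    else:
        tf = RigidTransform(0.0, (0.0, 0.0))
        registered = mov.copy()
    if isinstance(moving, SliceImage):
        registered = SliceImage(registered, spacing=moving.spacing)
    return tf, registered


# ---------------------------------------------------------------------------
# level-set displacement-field estimation


def estimate_displacement(moving, reference, params: LevelSetParams | None = None) -> DisplacementField:
    """Estimate the displacement field morphing ``moving`` toward ``reference``.

    Explicit-Euler iteration of the level-set motion equation with
    edge-replicated central-difference gradients on the currently warped image,
    Gaussian smoothing of the field each iteration, and residual-based step
    control: a step that would increase ``||I2 - I1(V)||`` is rejected and the
    time step halved; after ``divergence_limit`` consecutive rejections the
    iteration stops (raising :class:`ConvergenceError` if the residual never
    improved at all).

    The returned field satisfies ``warp(moving, field) ~= reference`` and its
    ``iteration_log`` holds the non-increasing accepted residual sequence.
    """
    if params is None:
        params = LevelSetParams()
    i1 = _as_pixels(moving)
    i2 = _as_pixels(reference)
    if i1.shape != i2.shape:
        raise ValueError("moving and reference must share a shape")

    # floor keeps eps_g out of the denormal range for (near-)constant images
    irange = max(float(np.ptp(i1)), float(np.ptp(i2)), 1e-6)
    eps_g = params.grad_eps * irange

    u = np.zeros_like(i1)
    w = np.zeros_like(i1)
    rows, cols = np.indices(i1.shape, dtype=float)

    def resample(uu, ww):
        return ndimage.map_coordinates(i1, [rows + ww, cols + uu], order=1, mode="nearest")

    warped = i1
    residual = float(np.linalg.norm(i2 - warped))
    log = [residual]
    dt = params.time_step
    rejected_streak = 0
    any_accepted = False

    for _ in range(params.max_iters):
        diff = i2 - warped
        gr, gc = np.gradient(warped)  # gr: d/drow, gc: d/dcol
        gmag = np.hypot(gc, gr)
        coef = diff / (gmag + eps_g)
        cand_u = u + dt * ndimage.gaussian_filter(coef * gc, params.smooth_sigma)
        cand_w = w + dt * ndimage.gaussian_filter(coef * gr, params.smooth_sigma)
        cand_warped = resample(cand_u, cand_w)
        cand_res = float(np.linalg.norm(i2 - cand_warped))
        if cand_res <= residual:
            rel_change = (residual - cand_res) / max(residual, np.finfo(float).tiny)
            u, w, warped = cand_u, cand_w, cand_warped
            residual = cand_res
            log.append(residual)
            any_accepted = True
            rejected_streak = 0
            if rel_change < params.stop_tol:
                break
        else:
            rejected_streak += 1
            dt *= 0.5
            if rejected_streak >= params.divergence_limit:
                if not any_accepted and cand_res > log[0]:
                    raise ConvergenceError(
                        "level-set iteration diverged: residual grew for "
                        f"{rejected_streak} consecutive steps", log,
                    )
                break

    return DisplacementField(u=u, w=w, iteration_log=log)


# ---------------------------------------------------------------------------
# polar conversion


def to_polar(dfield: DisplacementField) -> PolarField:
    """Convert a Cartesian field to magnitude/direction channels.

    magnitude = sqrt(u^2 + w^2); direction = atan2(w, u) wrapped to [0, 2*pi),
    with the convention direction = 0 wherever magnitude = 0 (the direction of
    a zero vector is undefined, so a fixed value keeps features deterministic).
    """
    mag = np.hypot(dfield.u, dfield.w)
    direction = np.mod(np.arctan2(dfield.w, dfield.u), 2.0 * np.pi)
    direction[mag == 0] = 0.0
    return PolarField(magnitude=mag, direction=direction)
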