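"""Deformable 2-D registration and Jacobian-determinant maps.

A coarse-to-fine demons-style matcher minimizes the sum of squared
differences between two soft-edged mask images under diffusion
regularization (Gaussian smoothing of the displacement field after each
update).  Binary masks are Gaussian-smoothed before matching because binary
SSD has flat gradients away from the boundary.

Conventions, fixed here and asserted by the test suite:

* A :class:`DeformationField` stores displacements ``u`` mapping *fixed*
  (template) coordinates to *moving* (subject) coordinates, i.e. the moving
  image resampled at ``x + u(x)`` matches the fixed image.
* The Jacobian determinant is ``det(I + grad u)`` by central finite
  differences (one-sided at borders); it is the local area ratio
  subject/template, so integrating it over a template-space label yields
  the subject-space area of that label.
* Non-positive determinants are never clamped; they are counted and
  reported so a folding field is diagnosed, not silently accepted.

Registration is fully deterministic: there is no stochastic initialization
anywhere in this module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import RegistrationError
from .io import MidsagittalMask


@dataclass(frozen=True)
class RegistrationSettings:
    """Multigrid demons settings.

    levels
        Downsampling factors, coarse to fine; level f works on a grid with
        spacing f pixels, mirroring a control grid of spacing f.
    iters_per_level
        Gradient-descent iterations at each level.
    field_sigma_px
        Diffusion regularization: Gaussian sigma (in level pixels) applied
        to the accumulated field after every update.
    update_sigma_px
        Fluid-like smoothing of each raw update before accumulation.
    image_sigma_px
        Pre-smoothing of binary masks into soft-edged images.
    step
        Update scaling; the demons force is already bounded by ~0.5 px.
    tol_px
        Mean-update early-stop threshold at the finest level.
    """

    levels: tuple[int, ...] = (4, 2, 1)
    iters_per_level: tuple[int, ...] = (100, 80, 60)
    field_sigma_px: float = 2.0
    update_sigma_px: float = 1.0
    image_sigma_px: float = 1.0
    step: float = 1.8
    tol_px: float = 1e-3
    max_step_px: float = 2.0

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.iters_per_level):
            raise RegistrationError("levels and iters_per_level lengths differ")


@dataclass
class DeformationField:
    """Template-to-subject displacement field.

    ``displacements`` has shape (2, rows, cols), in millimetres, on the
    template grid; component 0 displaces along rows, component 1 along
    columns.
    """

    displacements: np.ndarray
    spacing: tuple[float, float]
    subject_id: str = ""
    converged: bool = True

    def __post_init__(self) -> None:
        self.displacements = np.asarray(self.displacements, dtype=float)
        if self.displacements.ndim != 3 or self.displacements.shape[0] != 2:
            raise RegistrationError(
                "displacements must have shape (2, rows, cols)"
            )
        if not np.isfinite(self.displacements).all():
            raise RegistrationError(
                f"field {self.subject_id!r} contains non-finite displacements"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.displacements.shape[1:]


def smooth_mask_image(mask: MidsagittalMask, sigma_px: float = 1.0) -> np.ndarray:
    """Soft-edged float image of a binary mask (values in [0, 1])."""
    return ndimage.gaussian_filter(mask.pixels.astype(float), sigma_px)


def _resize(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    factors = (shape[0] / img.shape[0], shape[1] / img.shape[1])
    return ndimage.zoom(img, factors, order=1, mode="nearest", grid_mode=True)


def _downsample(img: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return img
    sm = ndimage.gaussian_filter(img, factor / 2.0)
    shape = (max(img.shape[0] // factor, 2), max(img.shape[1] // factor, 2))
    return _resize(sm, shape)


def warp_image(img: np.ndarray, u_px: np.ndarray, order: int = 1) -> np.ndarray:
    """Resample ``img`` at ``x + u_px`` (pixel-unit displacements)."""
    grid = np.mgrid[0 : img.shape[0], 0 : img.shape[1]].astype(float)
    coords = grid + u_px
    return ndimage.map_coordinates(img, coords, order=order, mode="constant", cval=0.0)


def _demons_level(
    fixed: np.ndarray,
    moving: np.ndarray,
    u: np.ndarray,
    settings: RegistrationSettings,
    iters: int,
) -> tuple[np.ndarray, float]:
    last_mean_update = np.inf
    for _ in range(iters):
        warped = warp_image(moving, u)
        diff = warped - fixed
        gr, gc = np.gradient(warped)
        g2 = gr**2 + gc**2
        denom = g2 + diff**2
        with np.errstate(invalid="ignore", divide="ignore"):
            fr = np.where(denom > 1e-12, -diff * gr / denom, 0.0)
            fc = np.where(denom > 1e-12, -diff * gc / denom, 0.0)
        upd = np.stack([fr, fc])
        if settings.update_sigma_px > 0:
            upd = ndimage.gaussian_filter(
                upd, (0, settings.update_sigma_px, settings.update_sigma_px)
            )
        upd *= settings.step
        np.clip(upd, -settings.max_step_px, settings.max_step_px, out=upd)
        u = u + upd
        if settings.field_sigma_px > 0:
            u = ndimage.gaussian_filter(
                u, (0, settings.field_sigma_px, settings.field_sigma_px)
            )
        last_mean_update = float(np.abs(upd).mean())
        if last_mean_update < settings.tol_px:
            break
    return u, last_mean_update


def register_images(
    moving: np.ndarray,
    fixed: np.ndarray,
    spacing: tuple[float, float],
    settings: RegistrationSettings = RegistrationSettings(),
    subject_id: str = "",
) -> DeformationField:
    """Register two soft-edged images already on a common grid."""
    if moving.shape != fixed.shape:
        raise RegistrationError(
            f"grid mismatch: moving {moving.shape} vs fixed {fixed.shape}"
        )
    u = None
    prev_shape = None
    mean_update = np.inf
    for level, iters in zip(settings.levels, settings.iters_per_level):
        fx = _downsample(fixed, level)
        mv = _downsample(moving, level)
        if u is None:
            u = np.zeros((2,) + fx.shape)
        else:
            scale = (fx.shape[0] / prev_shape[0], fx.shape[1] / prev_shape[1])
            u = np.stack(
                [_resize(u[0], fx.shape) * scale[0], _resize(u[1], fx.shape) * scale[1]]
            )
        u, mean_update = _demons_level(fx, mv, u, settings, iters)
        prev_shape = fx.shape
    if prev_shape != fixed.shape:  # finest level was subsampled
        scale = (fixed.shape[0] / prev_shape[0], fixed.shape[1] / prev_shape[1])
        u = np.stack(
            [_resize(u[0], fixed.shape) * scale[0], _resize(u[1], fixed.shape) * scale[1]]
        )
    converged = mean_update < 10 * settings.tol_px or mean_update < 0.05
    disp_mm = np.stack([u[0] * spacing[0], u[1] * spacing[1]])
    return DeformationField(
        displacements=disp_mm,
        spacing=spacing,
        subject_id=subject_id,
        converged=bool(converged),
    )


def register_pair(
    moving: MidsagittalMask | np.ndarray,
    fixed: np.ndarray,
    spacing: tuple[float, float] | None = None,
    settings: RegistrationSettings = RegistrationSettings(),
) -> DeformationField:
    """Register a subject mask (moving) to a template image (fixed).

    The mask is smoothed into a soft-edged image first; ``fixed`` is a
    float template image on the same grid.
    """
    if isinstance(moving, MidsagittalMask):
        sid = moving.subject_id
        if spacing is None:
            spacing = moving.spacing
        moving_img = smooth_mask_image(moving, settings.image_sigma_px)
    else:
        sid = ""
        moving_img = np.asarray(moving, dtype=float)
        if spacing is None:
            raise RegistrationError("spacing required for array inputs")
    return register_images(moving_img, np.asarray(fixed, float), spacing, settings, sid)


def field_to_pixels(fieldobj: DeformationField) -> np.ndarray:
    """Displacements in pixel units, shape (2, rows, cols)."""
    return np.stack(
        [
            fieldobj.displacements[0] / fieldobj.spacing[0],
            fieldobj.displacements[1] / fieldobj.spacing[1],
        ]
    )


def jacobian_map(fieldobj: DeformationField) -> np.ndarray:
    """Per-pixel determinant of ``I + grad u`` (unitless area ratio)."""
    u0, u1 = fieldobj.displacements
    dr, dc = fieldobj.spacing
    d00, d01 = np.gradient(u0, dr, dc)
    d10, d11 = np.gradient(u1, dr, dc)
    return (1.0 + d00) * (1.0 + d11) - d01 * d10


def count_nonpositive_jacobian(fieldobj: DeformationField) -> int:
    return int((jacobian_map(fieldobj) <= 0).sum())


def invert_field_px(u_px: np.ndarray, n_iter: int = 10) -> np.ndarray:
    """Fixed-point inverse of a displacement field (pixel units):
    v such that v(x) = -u(x + v(x))."""
    v = -u_px.copy()
    for _ in range(n_iter):
        v = -np.stack([warp_image(u_px[0], v), warp_image(u_px[1], v)])
    return v
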