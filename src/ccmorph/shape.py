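"""Bounding rectangle and bending-angle shape statistics.

The bending angle summarizes how arched the corpus callosum is: it is the
vertex angle of the isosceles triangle sharing the base and height of the
minimum rectangle circumscribing the ROI,

    angle = 2 * arctan( base / (2 * height) )   (reported in degrees),

so a flatter callosum (long base, low height) has a larger angle and a more
convex, strongly arched callosum a smaller one.

Two rectangle modes are provided. ``axis_aligned`` takes the tight
axis-aligned bounds of the foreground; it matches inputs that were already
aligned along the anterior-posterior commissure line.  ``min_area`` finds
the true minimum-area enclosing rectangle of the foreground convex hull
(edge-aligned search, exact by the classic rotating-calipers theorem).

Two pixel conventions are provided, because a "length" read off a pixel
grid is ambiguous by one pixel: ``pixel_extent`` (default) bounds whole
pixel squares, so a filled run of n pixels has length n * spacing, which is
self-consistent with pixel-count areas elsewhere in the package;
``pixel_center`` bounds pixel centers, giving (n - 1) * spacing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull

from .errors import EmptyMaskError, ValidationError, ZeroExtentRectangleError
from .io import MidsagittalMask

RECT_MODES = ("axis_aligned", "min_area")
PIXEL_CONVENTIONS = ("pixel_extent", "pixel_center")


@dataclass(frozen=True)
class BoundingRect:
    """Rectangle circumscribing a mask, in physical (mm) coordinates.

    ``corners`` is a (4, 2) array of (row_mm, col_mm) vertices ordered so
    that ``corners[0] -> corners[1]`` spans the base (the longer side) and
    ``corners[0] -> corners[3]`` the height.
    """

    base_mm: float
    height_mm: float
    corners: np.ndarray
    mode: str = "axis_aligned"

    def __post_init__(self) -> None:
        if not (self.base_mm >= self.height_mm > 0):
            raise ValidationError(
                f"rectangle requires base >= height > 0, got "
                f"base={self.base_mm}, height={self.height_mm}"
            )
        c = np.asarray(self.corners, dtype=float)
        if c.shape != (4, 2):
            raise ValidationError("corners must be a (4, 2) array")
        object.__setattr__(self, "corners", c)
        b, h = c[1] - c[0], c[3] - c[0]
        scale = max(self.base_mm, 1.0)
        if abs(float(b @ h)) > 1e-6 * scale**2:
            raise ValidationError("corners do not form a rectangle (not orthogonal)")
        if not np.allclose(c[2], c[0] + b + h, rtol=0, atol=1e-6 * scale):
            raise ValidationError("corners do not close up into a rectangle")
        if not math.isclose(float(np.linalg.norm(b)), self.base_mm, rel_tol=1e-6):
            raise ValidationError("base edge length disagrees with base_mm")
        if not math.isclose(float(np.linalg.norm(h)), self.height_mm, rel_tol=1e-6):
            raise ValidationError("height edge length disagrees with height_mm")

    @property
    def base_direction(self) -> np.ndarray:
        """Unit vector along the base, in (row, col) mm coordinates."""
        b = self.corners[1] - self.corners[0]
        return b / np.linalg.norm(b)

    @property
    def area_mm2(self) -> float:
        return self.base_mm * self.height_mm


@dataclass(frozen=True)
class BendingAngle:
    degrees: float

    def __post_init__(self) -> None:
        if not (0.0 < self.degrees < 180.0):
            raise ValidationError(
                f"bending angle must lie in (0, 180) degrees, got {self.degrees}"
            )


def _foreground_points(
    mask: MidsagittalMask, convention: str
) -> np.ndarray:
    """Physical coordinates representing the foreground.

    pixel_center: one point per pixel (its center).  pixel_extent: the four
    corners of each pixel square, so rectangles cover whole pixels.
    """
    idx = np.argwhere(mask.pixels).astype(float)
    dr, dc = mask.spacing
    if convention == "pixel_center":
        pts = (idx + 0.5) * (dr, dc)
    else:
        offsets = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        pts = (idx[:, None, :] + offsets[None]).reshape(-1, 2) * (dr, dc)
    return pts


def _rect_from_frame(
    origin: np.ndarray, u: np.ndarray, v: np.ndarray, len_u: float, len_v: float, mode: str
) -> BoundingRect:
    """Assemble a BoundingRect so that the base is the longer side."""
    if len_u < len_v:
        # re-anchor so corners[0]->corners[1] spans the longer side
        origin, u, v, len_u, len_v = origin, v, u, len_v, len_u
    corners = np.stack(
        [origin, origin + u * len_u, origin + u * len_u + v * len_v, origin + v * len_v]
    )
    return BoundingRect(base_mm=float(len_u), height_mm=float(len_v), corners=corners, mode=mode)


def bounding_rectangle(
    mask: MidsagittalMask,
    mode: str = "axis_aligned",
    convention: str = "pixel_extent",
) -> BoundingRect:
    """Minimum rectangle covering the mask foreground.

    Raises :class:`ZeroExtentRectangleError` when the foreground spans a
    single row or column (no 2-D rectangle exists).
    """
    if mode not in RECT_MODES:
        raise ValidationError(f"mode must be one of {RECT_MODES}, got {mode!r}")
    if convention not in PIXEL_CONVENTIONS:
        raise ValidationError(
            f"convention must be one of {PIXEL_CONVENTIONS}, got {convention!r}"
        )
    if not mask.pixels.any():
        raise EmptyMaskError("cannot bound an empty mask")
    rows, cols = np.nonzero(mask.pixels)
    if rows.min() == rows.max() or cols.min() == cols.max():
        raise ZeroExtentRectangleError(
            "zero-extent rectangle: foreground spans a single row or column"
        )
    dr, dc = mask.spacing
    if mode == "axis_aligned":
        if convention == "pixel_extent":
            r0, r1 = rows.min() * dr, (rows.max() + 1) * dr
            c0, c1 = cols.min() * dc, (cols.max() + 1) * dc
        else:
            r0, r1 = (rows.min() + 0.5) * dr, (rows.max() + 0.5) * dr
            c0, c1 = (cols.min() + 0.5) * dc, (cols.max() + 0.5) * dc
        return _rect_from_frame(
            np.array([r0, c0]),
            np.array([0.0, 1.0]),
            np.array([1.0, 0.0]),
            c1 - c0,
            r1 - r0,
            mode,
        )
    # min_area: search rectangles aligned with convex-hull edges
    pts = _foreground_points(mask, convention)
    hull = ConvexHull(pts)
    hp = pts[hull.vertices]
    edges = np.roll(hp, -1, axis=0) - hp
    best = None
    for e in edges:
        n = np.linalg.norm(e)
        if n < 1e-12:
            continue
        u = e / n
        v = np.array([-u[1], u[0]])
        pu, pv = hp @ u, hp @ v
        len_u, len_v = pu.max() - pu.min(), pv.max() - pv.min()
        area = len_u * len_v
        if best is None or area < best[0] - 1e-12:
            origin = pu.min() * u + pv.min() * v
            best = (area, origin, u, v, len_u, len_v)
    assert best is not None
    _, origin, u, v, len_u, len_v = best
    if min(len_u, len_v) <= 0:
        raise ZeroExtentRectangleError("zero-extent rectangle: degenerate hull")
    return _rect_from_frame(origin, u, v, len_u, len_v, mode)


def bending_angle(rect: BoundingRect) -> BendingAngle:
    """Vertex angle (degrees) of the isosceles triangle with the
    rectangle's base and height: ``2 * arctan(base / (2 * height))``."""
    return BendingAngle(
        degrees=math.degrees(2.0 * math.atan(rect.base_mm / (2.0 * rect.height_mm)))
    )


def angle_to_base_height_ratio(degrees: float) -> float:
    """Invert the bending-angle formula: return base/height for an angle."""
    if not (0.0 < degrees < 180.0):
        raise ValidationError("angle must lie in (0, 180) degrees")
    return 2.0 * math.tan(math.radians(degrees) / 2.0)
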