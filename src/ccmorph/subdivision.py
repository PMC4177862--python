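"""Proportional five-region subdivision of the corpus callosum.

Four cuts perpendicular to the longest side of the bounding rectangle split
the ROI into five contiguous slabs covering 33, 17, 17, 13 and 20 % of the
base length, ordered rostro-caudally: anterior third (rostrum + genu +
rostral body kept together), anterior mid-body, posterior mid-body, isthmus
and splenium.

Membership uses a half-open pixel-center rule — a pixel belongs to slab k
when the projection of its center onto the base axis falls in
``[start_k, end_k)``, with the last slab closed — so the partition is exact
(every foreground pixel gets exactly one label) and bit-reproducible.

Orientation is never guessed from the image.  The caller declares where the
anterior (genu) end of the callosum lies along the column axis:
``anterior_direction='+col'`` places it at the high-column end,
``'-col'`` at the low-column end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .io import REGION_NAMES, MidsagittalMask
from .shape import BoundingRect

DEFAULT_FRACTIONS = (0.33, 0.17, 0.17, 0.13, 0.20)
ANTERIOR_DIRECTIONS = ("+col", "-col")


@dataclass(frozen=True)
class SubregionLabelMap:
    """Integer label grid aligned with the source mask.

    0 is background; 1..5 follow :data:`ccmorph.io.REGION_NAMES` in
    rostro-caudal order.
    """

    labels: np.ndarray
    proportions: tuple[float, ...] = DEFAULT_FRACTIONS

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=np.int16))
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValidationError(
                f"proportions must sum to 1.0, got {sum(self.proportions)!r}"
            )

    def pixel_counts(self) -> np.ndarray:
        """Foreground pixel count per region, ordered 1..5."""
        return np.bincount(self.labels.ravel(), minlength=6)[1:6]


def _validate_fractions(fractions) -> tuple[float, ...]:
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 5 or any(f <= 0 for f in fractions):
        raise ValidationError("exactly five positive length fractions required")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValidationError(f"fractions must sum to 1.0, got {sum(fractions)}")
    return fractions


def subdivide(
    mask: MidsagittalMask,
    rect: BoundingRect,
    anterior_direction: str,
    fractions=DEFAULT_FRACTIONS,
) -> SubregionLabelMap:
    """Label each foreground pixel with its sub-region 1..5."""
    if anterior_direction not in ANTERIOR_DIRECTIONS:
        raise ValidationError(
            f"anterior_direction must be one of {ANTERIOR_DIRECTIONS}, "
            f"got {anterior_direction!r}"
        )
    fractions = _validate_fractions(fractions)

    idx = np.argwhere(mask.pixels)
    centers = (idx + 0.5) * mask.spacing  # (row_mm, col_mm)

    u = rect.base_direction
    if abs(u[1]) < 1e-9:
        raise ValidationError(
            "rectangle base is perpendicular to the column axis; cannot "
            "orient the anterior-posterior subdivision"
        )
    # orient u so it points from the anterior end toward the posterior end
    anterior_sign = 1.0 if anterior_direction == "+col" else -1.0
    if u[1] * anterior_sign > 0:  # u currently points anterior-ward
        u = -u
        start = rect.corners[1]
    else:
        start = rect.corners[0]

    t = (centers - start) @ u
    if t.min() < -0.5 * max(mask.spacing) or t.max() > rect.base_mm + 0.5 * max(
        mask.spacing
    ):
        raise ValidationError(
            "rectangle does not cover the mask (pixel centers project "
            "outside the base span)"
        )
    t = np.clip(t, 0.0, rect.base_mm)

    cuts = np.cumsum(fractions) * rect.base_mm
    # half-open [start_k, end_k); the last slab is closed at base_mm
    label_of = 1 + np.searchsorted(cuts[:-1], t, side="right")

    labels = np.zeros(mask.pixels.shape, dtype=np.int16)
    labels[idx[:, 0], idx[:, 1]] = label_of
    return SubregionLabelMap(labels=labels, proportions=fractions)


def region_pixel_areas(
    labelmap: SubregionLabelMap, spacing: tuple[float, float]
) -> np.ndarray:
    """Native pixel-count area (mm^2) of each of the five regions."""
    counts = labelmap.pixel_counts()
    if (counts == 0).any():
        empty = [REGION_NAMES[i] for i in np.nonzero(counts == 0)[0]]
        warnings.warn(f"regions with no pixels: {empty}", stacklevel=2)
    return counts * float(spacing[0]) * float(spacing[1])
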