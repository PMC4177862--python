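"""Readers and writers for masks, demographics and area tables.

The in-memory containers are deliberately small: a midsagittal corpus
callosum mask is a 2-D boolean grid plus its physical pixel spacing, and a
subject is a flat record joining the mask to group / sex / age / site and an
optional native-to-stereotaxic linear scaling factor.  Everything on disk is
a standard format: NIfTI-1 for masks and label maps, 8-bit PNG for quick
fixtures, RFC-4180 CSV for tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import (
    DimensionError,
    EmptyMaskError,
    MissingFileError,
    ValidationError,
)

GROUPS = ("CB", "NC")
SEXES = ("M", "F")

#: canonical rostro-caudal sub-region names, label values 1..5
REGION_NAMES = (
    "anterior_third",
    "anterior_midbody",
    "posterior_midbody",
    "isthmus",
    "splenium",
)

#: columns of a serialized area table, one row per subject x region
AREA_TABLE_COLUMNS = [
    "subject_id",
    "group",
    "sex",
    "age",
    "site",
    "linear_scale",
    "region",
    "stereotaxic_area_mm2",
    "native_area_mm2",
    "bending_deg",
    "base_mm",
    "height_mm",
    "rect_mode",
]


@dataclass
class MidsagittalMask:
    """One subject's corpus callosum ROI on the midsagittal plane.

    Parameters
    ----------
    pixels : ndarray of bool, shape (rows, cols)
        Foreground marks the callosal ROI. Rows run along the
        inferior-superior axis, columns along the anterior-posterior axis.
    spacing : (row_mm, col_mm)
        Physical size of one pixel in millimetres; the slice itself is
        assumed 1 mm thick so pixel areas are mm^2.
    subject_id : str
    """

    pixels: np.ndarray
    spacing: tuple[float, float]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2:
            raise DimensionError(
                f"mask must be 2-D, got {self.pixels.ndim}-D array"
            )
        self.spacing = (float(self.spacing[0]), float(self.spacing[1]))
        if self.spacing[0] <= 0 or self.spacing[1] <= 0:
            raise ValidationError(f"spacing must be positive, got {self.spacing}")
        if not self.pixels.any():
            raise EmptyMaskError(
                f"mask {self.subject_id!r} has no foreground pixels"
            )
        n_comp = ndimage.label(self.pixels)[1]
        if n_comp > 1:
            warnings.warn(
                f"mask {self.subject_id!r} has {n_comp} 4-connected "
                "components; expected a single connected ROI",
                stacklevel=2,
            )

    @property
    def pixel_area_mm2(self) -> float:
        return self.spacing[0] * self.spacing[1]

    @property
    def area_mm2(self) -> float:
        """Pixel-count area of the whole ROI."""
        return float(self.pixels.sum()) * self.pixel_area_mm2

    def __eq__(self, other) -> bool:  # masks compare by content
        return (
            isinstance(other, MidsagittalMask)
            and self.pixels.shape == other.pixels.shape
            and bool(np.all(self.pixels == other.pixels))
            and self.spacing == other.spacing
        )


@dataclass(frozen=True)
class SubjectRecord:
    """Demographics and scaling for one subject."""

    subject_id: str
    group: str
    sex: str
    age: float
    site: str = "site1"
    linear_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(
                f"subject {self.subject_id!r}: group {self.group!r} "
                f"not in {GROUPS}"
            )
        if self.sex not in SEXES:
            raise ValidationError(
                f"subject {self.subject_id!r}: sex {self.sex!r} not in {SEXES}"
            )
        if not np.isfinite(self.age) or self.age <= 0:
            raise ValidationError(
                f"subject {self.subject_id!r}: age must be positive, "
                f"got {self.age}"
            )
        if self.linear_scale <= 0:
            raise ValidationError(
                f"subject {self.subject_id!r}: linear_scale must be positive"
            )


def _load_nifti_2d(path: Path) -> tuple[np.ndarray, tuple[float, float]]:
    img = nib.load(str(path))
    if img.ndim == 3:
        # reorient to the closest canonical axes so that on-disk storage
        # order / flips do not change the in-memory mask
        img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj).astype(float)
    zooms = img.header.get_zooms()[: data.ndim]
    keep = [ax for ax in range(data.ndim) if data.shape[ax] > 1]
    if len(keep) > 2:
        raise DimensionError(
            f"{path}: expected a 2-D image (or 3-D with a singleton axis), "
            f"got shape {data.shape}"
        )
    if data.ndim == 3:
        drop = [ax for ax in range(3) if ax not in keep]
        # keep at most one dropped axis ambiguity: squeeze all singletons
        data = np.squeeze(data, axis=tuple(drop))
        zooms = tuple(zooms[ax] for ax in keep)
    if data.ndim < 2:  # degenerate, e.g. shape (N, 1, 1)
        raise DimensionError(f"{path}: image is not two-dimensional")
    return data, (float(zooms[0]), float(zooms[1]))


def read_mask(
    path: str | Path,
    binarize_threshold: float = 0.5,
    spacing: tuple[float, float] | None = None,
    subject_id: str | None = None,
) -> MidsagittalMask:
    """Read a binary CC mask from NIfTI (preferred) or PNG.

    Intensities are normalized to [0, 1] by the image maximum before
    thresholding, so ``binarize_threshold`` is on normalized intensity
    (default 0.5).  For NIfTI the pixel spacing comes from the header unless
    overridden; PNG carries no spacing, so it must be supplied.
    """
    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"mask file not found: {path}")
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        data, header_spacing = _load_nifti_2d(path)
        if spacing is None:
            spacing = header_spacing
    elif suffixes.endswith(".png"):
        arr = iio.imread(path)
        if arr.ndim == 3:  # RGB(A) -> luminance
            arr = arr[..., :3].mean(axis=-1)
        data = arr.astype(float)
        if spacing is None:
            raise ValidationError(
                f"{path}: PNG carries no pixel spacing; pass spacing=(row_mm, col_mm)"
            )
    else:
        raise DimensionError(
            f"{path}: unsupported mask format (use .nii, .nii.gz or .png)"
        )
    peak = float(np.max(data))
    if peak <= 0:
        raise EmptyMaskError(f"{path}: image is empty (all zeros)")
    pixels = (data / peak) > binarize_threshold
    if not pixels.any():
        raise EmptyMaskError(f"{path}: no pixels above threshold")
    return MidsagittalMask(
        pixels=pixels,
        spacing=spacing,
        subject_id=subject_id if subject_id is not None else path.stem.split(".")[0],
    )


def _mask_affine(spacing: tuple[float, float]) -> np.ndarray:
    return np.diag([spacing[0], spacing[1], 1.0, 1.0])


def write_mask(mask: MidsagittalMask, path: str | Path) -> None:
    """Write a mask as a 3-D NIfTI with a singleton third axis."""
    data = mask.pixels.astype(np.uint8)[..., None]
    img = nib.Nifti1Image(data, _mask_affine(mask.spacing))
    img.header.set_zooms((mask.spacing[0], mask.spacing[1], 1.0))
    nib.save(img, str(path))


def write_labelmap(
    labels: np.ndarray, spacing: tuple[float, float], path: str | Path
) -> None:
    """Write an integer sub-region label map sharing the mask grid."""
    img = nib.Nifti1Image(
        np.asarray(labels, dtype=np.int16)[..., None], _mask_affine(spacing)
    )
    nib.save(img, str(path))


def read_labelmap(path: str | Path) -> tuple[np.ndarray, tuple[float, float]]:
    data, spacing = _load_nifti_2d(Path(path))
    return np.rint(data).astype(np.int16), spacing


_REQUIRED_DEMO_COLUMNS = ("subject_id", "group", "sex", "age")


def read_demographics(path: str | Path) -> list[SubjectRecord]:
    """Read a demographics CSV into validated :class:`SubjectRecord` rows.

    Required columns: subject_id, group (CB/NC), sex (M/F), age.  Optional:
    site (default ``site1``) and linear_scale (default 1.0).
    """
    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"demographics file not found: {path}")
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in _REQUIRED_DEMO_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    if df.empty:
        warnings.warn(f"{path}: demographics table is empty", stacklevel=2)
        return []
    dupes = df["subject_id"][df["subject_id"].duplicated()].tolist()
    if dupes:
        raise ValidationError(f"{path}: duplicate subject ids {sorted(set(dupes))}")
    ages = pd.to_numeric(df["age"], errors="coerce")
    if ages.isna().any():
        bad = df.loc[ages.isna(), "subject_id"].tolist()
        raise ValidationError(f"{path}: unparsable age for subjects {bad}")
    records = []
    for row, age in zip(df.itertuples(index=False), ages):
        records.append(
            SubjectRecord(
                subject_id=str(row.subject_id),
                group=str(row.group),
                sex=str(row.sex),
                age=float(age),
                site=str(getattr(row, "site", "site1")),
                linear_scale=float(getattr(row, "linear_scale", 1.0)),
            )
        )
    return records


def write_demographics(records: Sequence[SubjectRecord], path: str | Path) -> None:
    pd.DataFrame([r.__dict__ for r in records]).to_csv(path, index=False)


def write_area_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write an area table (one row per subject x region) to CSV.

    The round trip through :func:`read_area_table` is lossless: floats are
    written with full ``repr`` precision.
    """
    if table.empty:
        raise ValidationError("refusing to write an empty area table")
    unknown = set(table["region"]) - set(REGION_NAMES) - {"total"}
    if unknown:
        raise ValidationError(f"unknown region labels {sorted(unknown)}")
    cols = [c for c in AREA_TABLE_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    table[cols].to_csv(path, index=False, float_format=None)


def read_area_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"area table not found: {path}")
    return pd.read_csv(path, dtype={"subject_id": str})
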