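"""Synthetic corpus-callosum cohorts with planted, recoverable geometry.

Real midsagittal masks for the congenitally-blind (CB) vs sighted-control
(NC) comparison are not redistributable, so every downstream stage is
exercised on synthetic cohorts instead, at two levels of realism:

* :func:`make_cc_shape` draws a single arch-shaped mask whose bounding
  rectangle (hence bending angle) and per-sub-region pixel areas are
  controlled exactly.  The centerline is a half-ellipse spanning the base
  with its apex at ``height - thickness/2``; each of the five proportional
  slabs is thickened vertically by its own constant thickness chosen so the
  slab's pixel-count area equals the planted area.  Pixel counts are
  distributed across columns by cumulative rounding, so each planted area
  is met to within half a pixel.

* :func:`sample_mask_cohort` draws per-subject sub-region areas and bending
  angles from group-specific normal distributions (truncated at 3 SD and at
  geometric feasibility), inverts the bending-angle formula to get the
  rectangle height, and builds one mask per subject.

* :func:`simulate_area_table` skips imaging entirely and emits a numeric
  area table drawn from the same (untruncated) normals, for calibrating and
  testing the statistics on their own.

The shipped defaults (``ccmorph/data/cohort_defaults.yaml``) encode the
study conditions this package emulates: n = 28 per group with 16 males and
12 females each, splenium 260.84 +/- 41.7 mm^2 (NC) vs 225.64 +/- 31.7 mm^2
(CB), posterior mid-body 89.64 +/- 16.51 vs 107.26 +/- 21.67 mm^2, isthmus
64.16 +/- 10.31 vs 79.4 +/- 16.66 mm^2, bending angle 113.4 +/- 5.7 vs
109.6 +/- 4.9 degrees, ages 19-63.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import InfeasibleShapeError, ValidationError
from .io import REGION_NAMES, MidsagittalMask, SubjectRecord
from .shape import angle_to_base_height_ratio
from .subdivision import DEFAULT_FRACTIONS

#: sites are assigned cyclically with these weights (8:11:9, the
#: three-scanner recruitment ratio of the emulated study design)
SITE_WEIGHTS = {"siteA": 8, "siteB": 11, "siteC": 9}

#: sex-specific isthmus cells (mean mm^2, SD mm^2, n) of the emulated study
#: design; used for group-by-sex interaction recovery simulations
ISTHMUS_CELLS = {
    ("CB", "M"): (87.24, 18.81, 16),
    ("CB", "F"): (68.95, 11.83, 12),
    ("NC", "M"): (63.49, 10.05, 16),
    ("NC", "F"): (65.06, 11.04, 12),
}


@dataclass(frozen=True)
class CCShapeParams:
    """Geometry of one synthetic mask."""

    base_mm: float
    height_mm: float
    region_areas_mm2: tuple[float, float, float, float, float]
    spacing_mm: float = 1.0
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS

    def __post_init__(self) -> None:
        if self.base_mm <= 0 or self.height_mm <= 0 or self.spacing_mm <= 0:
            raise ValidationError("base, height and spacing must be positive")
        if len(self.region_areas_mm2) != 5 or any(
            a <= 0 for a in self.region_areas_mm2
        ):
            raise ValidationError("five positive region areas required")


@dataclass(frozen=True)
class GroupSpec:
    """Per-group population parameters (means and SDs)."""

    n: int
    n_male: int
    region_means_mm2: tuple[float, float, float, float, float]
    region_sds_mm2: tuple[float, float, float, float, float]
    angle_mean_deg: float
    angle_sd_deg: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError("need at least 2 subjects per group")
        if not (0 <= self.n_male <= self.n):
            raise ValidationError("n_male must lie in [0, n]")
        if any(s < 0 for s in self.region_sds_mm2) or self.angle_sd_deg < 0:
            raise ValidationError("SDs must be non-negative")


@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort description (the synthetic study conditions)."""

    groups: dict[str, GroupSpec]
    base_mm: float = 100.0
    spacing_mm: float = 1.0
    age_range: tuple[float, float] = (19.0, 63.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValidationError("cohort needs at least one group")
        if self.age_range[0] <= 0 or self.age_range[1] < self.age_range[0]:
            raise ValidationError(f"bad age range {self.age_range}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "CohortSpec":
        groups = {
            name: GroupSpec(
                n=int(g["n"]),
                n_male=int(g["n_male"]),
                region_means_mm2=tuple(float(x) for x in g["region_means_mm2"]),
                region_sds_mm2=tuple(float(x) for x in g["region_sds_mm2"]),
                angle_mean_deg=float(g["angle_mean_deg"]),
                angle_sd_deg=float(g["angle_sd_deg"]),
            )
            for name, g in raw["groups"].items()
        }
        return cls(
            groups=groups,
            base_mm=float(raw.get("base_mm", 100.0)),
            spacing_mm=float(raw.get("spacing_mm", 1.0)),
            age_range=tuple(raw.get("age_range", (19.0, 63.0))),
            seed=int(raw.get("seed", 0)),
        )

    @classmethod
    def default(cls, seed: int = 0) -> "CohortSpec":
        """The packaged CB/NC study conditions."""
        path = resources.files("ccmorph.data") / "cohort_defaults.yaml"
        spec = cls.from_yaml(str(path))
        return cls(
            groups=spec.groups,
            base_mm=spec.base_mm,
            spacing_mm=spec.spacing_mm,
            age_range=spec.age_range,
            seed=seed,
        )


def _slab_columns(n_cols: int, spacing: float, fractions) -> np.ndarray:
    """Slab index (0..4) of each column, by the same half-open
    pixel-center rule the subdivision module uses."""
    centers = (np.arange(n_cols) + 0.5) * spacing
    cuts = np.cumsum(fractions) * n_cols * spacing
    return np.searchsorted(cuts[:-1], centers, side="right")


def required_thicknesses(params: CCShapeParams) -> np.ndarray:
    """Per-slab thickness (mm) needed to realise the planted areas."""
    n_cols = int(round(params.base_mm / params.spacing_mm))
    slab = _slab_columns(n_cols, params.spacing_mm, params.fractions)
    widths = np.bincount(slab, minlength=5) * params.spacing_mm
    if (widths == 0).any():
        raise InfeasibleShapeError("base too short: a slab has zero columns")
    return np.asarray(params.region_areas_mm2) / widths


def check_feasible(params: CCShapeParams) -> None:
    """Raise :class:`InfeasibleShapeError` if any slab needs a thickness
    above half the arch height, or dimensions are sub-pixel."""
    if params.base_mm < 5 * params.spacing_mm or params.height_mm < 2 * params.spacing_mm:
        raise InfeasibleShapeError(
            f"degenerate dimensions: base={params.base_mm} mm, "
            f"height={params.height_mm} mm at {params.spacing_mm} mm spacing"
        )
    thick = required_thicknesses(params)
    limit = params.height_mm / 2.0
    for name, t in zip(REGION_NAMES, thick):
        if t > limit:
            raise InfeasibleShapeError(
                f"{name} needs thickness {t:.2f} mm > height/2 = {limit:.2f} mm"
            )
        if t < params.spacing_mm:
            raise InfeasibleShapeError(
                f"{name} needs sub-pixel thickness {t:.2f} mm at "
                f"{params.spacing_mm} mm spacing"
            )


def make_cc_shape(params: CCShapeParams, subject_id: str = "synthetic") -> MidsagittalMask:
    """Build an arch-shaped mask with planted rectangle and slab areas."""
    check_feasible(params)
    sp = params.spacing_mm
    n_cols = int(round(params.base_mm / sp))
    n_rows = int(round(params.height_mm / sp))
    slab = _slab_columns(n_cols, sp, params.fractions)
    thick_px = required_thicknesses(params) / sp

    # distribute each slab's target pixel count over its columns by
    # cumulative rounding, so the slab total is exact to the rounded count
    counts = np.zeros(n_cols, dtype=int)
    for k in range(5):
        cols_k = np.nonzero(slab == k)[0]
        target = params.region_areas_mm2[k] / sp**2
        cum = np.rint(np.arange(1, cols_k.size + 1) * target / cols_k.size).astype(int)
        counts[cols_k] = np.diff(np.concatenate(([0], cum)))
    if (counts <= 0).any():
        raise InfeasibleShapeError("a column received no pixels; area too small")
    if (counts > n_rows).any():
        raise InfeasibleShapeError("a column exceeds the arch height")

    # half-ellipse lower envelope: 0 at the end columns, height - thickness
    # at the apex, so the mask spans the full planted rectangle
    x = np.arange(n_cols) + 0.5
    xi = (x - n_cols / 2.0) / max((n_cols - 1) / 2.0, 1e-9)
    s = np.sqrt(np.clip(1.0 - xi**2, 0.0, None))
    lower = np.rint((n_rows - thick_px[slab]) * s).astype(int)
    lower = np.clip(lower, 0, n_rows - counts)

    # single left-to-right pass enforcing 4-connectivity between adjacent
    # column bands by shifting (never resizing) a band
    for j in range(1, n_cols):
        lo, hi = lower[j - 1], lower[j - 1] + counts[j - 1] - 1
        lower[j] = np.clip(lower[j], lo - counts[j] + 1, hi)
        lower[j] = np.clip(lower[j], 0, n_rows - counts[j])

    pixels = np.zeros((n_rows, n_cols), dtype=bool)
    for j in range(n_cols):
        pixels[lower[j] : lower[j] + counts[j], j] = True
    return MidsagittalMask(pixels=pixels, spacing=(sp, sp), subject_id=subject_id)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal draw truncated at 3 SD (a deliberate deviation from the pure
    normal model, to keep geometry sane)."""
    if sd == 0:
        return mean
    while True:
        x = rng.normal(mean, sd)
        if abs(x - mean) <= 3.0 * sd:
            return x


def _sites_for(n: int) -> list[str]:
    names = [s for s, w in SITE_WEIGHTS.items() for _ in range(w)]
    return [names[i % len(names)] for i in range(n)]


def _draw_subject_params(
    rng: np.random.Generator, group: GroupSpec, base_mm: float, spacing_mm: float
) -> CCShapeParams:
    last_err: Exception | None = None
    for _ in range(100):
        areas = tuple(
            _truncated_normal(rng, m, s)
            for m, s in zip(group.region_means_mm2, group.region_sds_mm2)
        )
        angle = _truncated_normal(rng, group.angle_mean_deg, group.angle_sd_deg)
        height = base_mm / angle_to_base_height_ratio(angle)
        params = CCShapeParams(
            base_mm=base_mm,
            height_mm=height,
            region_areas_mm2=areas,
            spacing_mm=spacing_mm,
        )
        try:
            check_feasible(params)
            return params
        except InfeasibleShapeError as err:
            last_err = err
    raise InfeasibleShapeError(
        f"100 consecutive infeasible draws for this group; last failure: {last_err}"
    )


def sample_mask_cohort(
    spec: CohortSpec,
) -> tuple[list[MidsagittalMask], list[SubjectRecord]]:
    """Draw one mask + demographics record per subject.

    A single :class:`numpy.random.SeedSequence` seeded with ``spec.seed``
    is spawned once per subject, so any subject can be regenerated in
    isolation and the cohort is bit-reproducible.
    """
    root = np.random.SeedSequence(spec.seed)
    total = sum(g.n for g in spec.groups.values())
    children = root.spawn(total)
    masks: list[MidsagittalMask] = []
    records: list[SubjectRecord] = []
    i = 0
    for gname, group in sorted(spec.groups.items()):
        sites = _sites_for(group.n)
        for k in range(group.n):
            rng = np.random.default_rng(children[i])
            params = _draw_subject_params(rng, group, spec.base_mm, spec.spacing_mm)
            sid = f"{gname.lower()}{k + 1:02d}"
            masks.append(make_cc_shape(params, subject_id=sid))
            records.append(
                SubjectRecord(
                    subject_id=sid,
                    group=gname,
                    sex="M" if k < group.n_male else "F",
                    age=float(rng.uniform(*spec.age_range)),
                    site=sites[k],
                    linear_scale=1.0,
                )
            )
            i += 1
    return masks, records


def planted_region_areas(mask_params: CCShapeParams) -> np.ndarray:
    return np.asarray(mask_params.region_areas_mm2, dtype=float)


def simulate_cell_table(
    cells: dict[tuple[str, str], tuple[float, float, int]],
    seed: int | np.random.Generator,
    region: str = "isthmus",
    age_range: tuple[float, float] = (19.0, 63.0),
) -> pd.DataFrame:
    """One replicate of a group-by-sex cell simulation for a single region.

    ``cells`` maps (group, sex) to (mean, SD, n); areas are independent
    normal draws, ages independent uniforms.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    rows = []
    i = 0
    for (gname, sex), (mean, sd, n) in sorted(cells.items()):
        for _ in range(n):
            i += 1
            area = float(rng.normal(mean, sd))
            rows.append(
                {
                    "subject_id": f"s{i:03d}",
                    "group": gname,
                    "sex": sex,
                    "age": float(rng.uniform(*age_range)),
                    "site": "siteA",
                    "linear_scale": 1.0,
                    "region": region,
                    "stereotaxic_area_mm2": area,
                    "native_area_mm2": area,
                }
            )
    return pd.DataFrame(rows)


def simulate_area_table(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Numeric area cohort drawn straight from the group normals.

    No masks are involved; areas are independent normal draws per region
    (not truncated), ages uniform on ``spec.age_range``, and the linear
    scale is 1 so stereotaxic and native areas coincide.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    rows = []
    for gname, group in sorted(spec.groups.items()):
        sites = _sites_for(group.n)
        for k in range(group.n):
            sid = f"{gname.lower()}{k + 1:02d}"
            sex = "M" if k < group.n_male else "F"
            age = float(rng.uniform(*spec.age_range))
            angle = float(rng.normal(group.angle_mean_deg, group.angle_sd_deg))
            height = spec.base_mm / angle_to_base_height_ratio(angle)
            for region, m, s in zip(
                REGION_NAMES, group.region_means_mm2, group.region_sds_mm2
            ):
                area = float(rng.normal(m, s))
                rows.append(
                    {
                        "subject_id": sid,
                        "group": gname,
                        "sex": sex,
                        "age": age,
                        "site": sites[k],
                        "linear_scale": 1.0,
                        "region": region,
                        "stereotaxic_area_mm2": area,
                        "native_area_mm2": area,
                        "bending_deg": angle,
                        "base_mm": spec.base_mm,
                        "height_mm": height,
                        "rect_mode": "axis_aligned",
                    }
                )
    return pd.DataFrame(rows)
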