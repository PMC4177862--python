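"""Pipeline configuration (YAML-serializable)."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ValidationError
from .registration import RegistrationSettings
from .shape import RECT_MODES
from .subdivision import ANTERIOR_DIRECTIONS, DEFAULT_FRACTIONS
from .synthetic import CohortSpec
from .template import TemplateSettings


@dataclass
class PipelineConfig:
    """Everything needed for one reproducible end-to-end run.

    input mode is either ``synthetic`` (a cohort spec drives the mask
    generator) or ``masks_dir`` (a directory of NIfTI masks plus a
    demographics CSV).
    """

    mode: str = "synthetic"
    out_dir: str = "ccmorph_out"
    seed: int = 0
    cohort: dict | None = None  # CohortSpec fields for synthetic mode
    masks_dir: str | None = None
    demographics: str | None = None
    anterior_direction: str = "-col"
    rect_mode: str = "axis_aligned"
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS
    stats_space: str = "stereotaxic"  # or "native"
    registration: dict = field(default_factory=dict)
    n_template_iterations: int = 4
    field_sigma_schedule_px: tuple[float, ...] = (8.0, 4.0, 2.0, 1.0)

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "masks_dir"):
            raise ValidationError(f"unknown input mode {self.mode!r}")
        if self.anterior_direction not in ANTERIOR_DIRECTIONS:
            raise ValidationError(
                f"anterior_direction must be one of {ANTERIOR_DIRECTIONS}"
            )
        if self.rect_mode not in RECT_MODES:
            raise ValidationError(f"rect_mode must be one of {RECT_MODES}")
        self.fractions = tuple(float(f) for f in self.fractions)
        if len(self.fractions) != 5 or abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValidationError(
                f"fractions must be five values summing to 1.0, got {self.fractions}"
            )
        if self.stats_space not in ("stereotaxic", "native"):
            raise ValidationError("stats_space must be 'stereotaxic' or 'native'")
        if self.mode == "synthetic" and self.seed is None:
            raise ValidationError("synthetic mode requires a seed")
        if self.mode == "masks_dir" and not (self.masks_dir and self.demographics):
            raise ValidationError(
                "masks_dir mode requires masks_dir and demographics paths"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fractions"] = list(self.fractions)
        d["field_sigma_schedule_px"] = list(self.field_sigma_schedule_px)
        return d

    def cohort_spec(self) -> CohortSpec:
        if self.cohort is None:
            return CohortSpec.default(seed=self.seed)
        spec = CohortSpec.from_dict(self.cohort)
        return CohortSpec(
            groups=spec.groups,
            base_mm=spec.base_mm,
            spacing_mm=spec.spacing_mm,
            age_range=spec.age_range,
            seed=self.seed,
        )

    def template_settings(self) -> TemplateSettings:
        reg = RegistrationSettings(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in self.registration.items()
        })
        return TemplateSettings(
            n_iterations=self.n_template_iterations,
            field_sigma_schedule_px=tuple(self.field_sigma_schedule_px),
            registration=reg,
        )
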