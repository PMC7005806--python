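"""Structured pipeline configuration with strict validation."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import yaml

from .feature_registration import RegistrationConfig
from .types import ValidationError

__all__ = ["PipelineConfig", "validate_config"]


@dataclass
class PipelineConfig:
    """Everything an end-to-end run needs; serialized alongside its outputs."""

    src: str | None = None              # moving gray volume (full resolution)
    moving_labels: str | None = None    # regional-feature labels, moving space
    fixed_labels: str | None = None     # regional-feature labels, fixed space
    out: str = "brainsmapi_out"
    working_voxel_um: float = 10.0      # resolution at which transforms are obtained
    regions: list | None = None         # default: all labels shared by both volumes
    encoding: str = "onehot"
    scale: float = 1.0                  # high-res/low-res quotient s for block warping
    block_size: int = 32
    margin: int | None = None
    workers: int = 1
    interp: str = "linear"
    reslice_axis: str = "z"
    seed: int = 0
    registration: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        if self.working_voxel_um <= 0:
            raise ValidationError("working_voxel_um must be > 0")
        if self.block_size < 8:
            raise ValidationError(f"block_size must be >= 8, got {self.block_size}")
        if self.workers < 1:
            raise ValidationError("workers must be >= 1")
        if self.interp not in ("linear", "nearest"):
            raise ValidationError(f"interp must be linear|nearest, got {self.interp!r}")
        if self.reslice_axis not in ("x", "y", "z"):
            raise ValidationError("reslice_axis must be x|y|z")
        reg_fields = {f.name for f in dataclasses.fields(RegistrationConfig)}
        unknown = set(self.registration) - reg_fields
        if unknown:
            raise ValidationError(f"unknown registration keys: {sorted(unknown)}")

    def registration_config(self) -> RegistrationConfig:
        kw = dict(self.registration)
        kw.setdefault("seed", self.seed)
        for k in ("levels", "iters_per_level"):
            if k in kw:
                kw[k] = tuple(kw[k])
        return RegistrationConfig(**kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def validate_config(path) -> PipelineConfig:
    """Parse a YAML/JSON config file; unknown keys are rejected by name."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ValidationError("config file must hold a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)
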