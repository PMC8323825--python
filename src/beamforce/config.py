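"""Run configuration: schema-validated YAML with defaults filled in.

Unknown keys are rejected (pydantic ``extra='forbid'``) so a typo in a
config file fails loudly with the offending key named.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .profile_pipeline import DetectionConfig
from .registry import default_registry

__all__ = ["RunConfig", "StudySection", "DetectionSection", "load_config", "save_config"]


class DetectionSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    drop_fraction: float = Field(default=0.05, gt=0, lt=1)
    drop_window_s: float = Field(default=0.1, gt=0)
    min_drop_mn: float = Field(default=0.2, ge=0)
    plateau_window_s: float = Field(default=2.0, gt=0)
    plateau_slope_mn_s: float = Field(default=0.05, gt=0)
    buckling_tolerance: float = Field(default=0.30, gt=0)
    contact_noise_mult: float = Field(default=3.0, gt=0)

    def to_detection(self) -> DetectionConfig:
        return DetectionConfig(**self.model_dump())


class StudySection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_animals: int = Field(default=8, ge=1)
    intercept_mn: float = 0.2
    slope_mn_per_um: float = 0.028
    sharp_tip_multiplier: float = Field(default=0.6, gt=0)
    dura_multiplier: float = Field(default=15.0, gt=0)
    animal_sd: float = Field(default=0.0, ge=0)
    residual_sd: float = Field(default=0.3, ge=0)
    dimpling_noise_sd_mm: float = Field(default=0.05, ge=0)


class TraceSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_traces: int = Field(default=5, ge=0)
    membrane_stiffness_mn_mm: float = Field(default=3.0, gt=0)
    rupture_force_mn: float = Field(default=3.0, gt=0)
    breathing_amplitude_mn: float = Field(default=0.05, ge=0)
    sensor_noise_sd_um: float = Field(default=0.05, ge=0)


class RunConfig(BaseModel):
    """Top-level run configuration (see package docs for field meanings)."""

    model_config = ConfigDict(extra="forbid")

    beam: str = "beam1"
    calibration_source: str = Field(default="fem", pattern="^(fem|ideal|experiment)$")
    sample_rate_hz: float = Field(default=500.0, gt=0)
    insertion_rate_um_s: float = Field(default=100.0, gt=0)
    seed: int = 0
    outdir: str = "results/run"
    traces_dir: str | None = None
    verbosity: str = Field(default="info", pattern="^(debug|info|warning)$")
    detection: DetectionSection = DetectionSection()
    study: StudySection = StudySection()
    trace: TraceSection = TraceSection()

    def validate_against_registry(self) -> "RunConfig":
        registry = default_registry()
        if self.beam not in registry.beams:
            raise ValueError(
                f"unknown beam '{self.beam}'; registry has {sorted(registry.beams)}"
            )
        return self

    def content_hash(self) -> str:
        blob = yaml.safe_dump(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML run config (or defaults when ``path`` is None).

    Keyword overrides (e.g. ``seed=7``) are applied after the file.
    Schema violations raise ``ValueError`` naming the offending key.
    """
    raw: dict = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(p)
        raw = yaml.safe_load(p.read_text()) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    try:
        cfg = RunConfig.model_validate(raw)
    except ValidationError as exc:
        first = exc.errors()[0]
        key = ".".join(str(loc) for loc in first["loc"]) or "<root>"
        raise ValueError(f"invalid config key '{key}': {first['msg']}") from exc
    return cfg.validate_against_registry()


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=True))
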