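"""Packaged instrument registry: the four sensing beams, the laser sensor,
calibration coefficient tables, and the microwire stock.

The registry ships as ``data/system.yaml`` inside the package and is
schema-validated with pydantic on load; unknown keys are rejected so typos
in a user-supplied override file fail loudly.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .beam_mechanics import (
    BeamSpec,
    CalibrationMap,
    CalibrationSource,
    LaserSpec,
    TipGeometry,
    WireMaterial,
    WireSpec,
    ideal_calibration,
)

__all__ = ["SystemRegistry", "load_registry", "default_registry"]


class _LaserModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    height_from_base_mm: float = Field(gt=0)
    range_mm: float = Field(gt=0)
    resolution_um: float = Field(gt=0)


class _BeamModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    material: str
    elastic_modulus_gpa: float = Field(gt=0)
    length_mm: float = Field(gt=0)
    thickness_mm: float = Field(gt=0)
    width_mm: float = Field(gt=0)


class _CalibModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    force_per_laser_deflection: float = Field(gt=0)
    loadpoint_per_laser_deflection: float = Field(gt=0)


class _MaterialModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    elastic_modulus_gpa: float = Field(gt=0)


class _WiresModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    materials: dict[str, _MaterialModel]
    overhang_mm: dict[str, float]
    diameters_um: list[float]
    tip_geometries: list[str]


class _SystemModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    laser: _LaserModel
    clamp_height_mm: float = Field(gt=0)
    beams: dict[str, _BeamModel]
    calibration: dict[str, dict[str, _CalibModel]]
    wires: _WiresModel

    @model_validator(mode="after")
    def _calibration_names_exist(self) -> "_SystemModel":
        for source, table in self.calibration.items():
            if source not in ("fem", "experiment"):
                raise ValueError(f"unknown calibration source '{source}'")
            for beam_name in table:
                if beam_name not in self.beams:
                    raise ValueError(f"calibration refers to unknown beam '{beam_name}'")
        return self


class SystemRegistry:
    """Validated view of the instrument configuration."""

    def __init__(self, model: _SystemModel):
        self._model = model
        self.laser = LaserSpec(
            height_from_base=model.laser.height_from_base_mm * 1e-3,
            range=model.laser.range_mm * 1e-3,
            resolution=model.laser.resolution_um * 1e-6,
        )
        self.beams: dict[str, BeamSpec] = {
            name: BeamSpec.from_bench(
                name=name,
                elastic_modulus_gpa=b.elastic_modulus_gpa,
                length_mm=b.length_mm,
                thickness_mm=b.thickness_mm,
                width_mm=b.width_mm,
                clamp_height_mm=model.clamp_height_mm,
            )
            for name, b in model.beams.items()
        }

    @property
    def beam_names(self) -> list[str]:
        return list(self.beams)

    def beam(self, name: str) -> BeamSpec:
        try:
            return self.beams[name]
        except KeyError:
            raise KeyError(
                f"unknown beam '{name}'; registry has {sorted(self.beams)}"
            ) from None

    def calibration(self, beam_name: str, source: CalibrationSource | str) -> CalibrationMap:
        """CalibrationMap for a beam from one source (fem / experiment / ideal)."""
        source = CalibrationSource(source)
        beam = self.beam(beam_name)
        if source is CalibrationSource.IDEAL:
            return ideal_calibration(beam, self.laser)
        table = self._model.calibration.get(source.value, {})
        if beam_name not in table:
            raise KeyError(f"no {source.value} calibration for beam '{beam_name}'")
        row = table[beam_name]
        return CalibrationMap(
            force_per_laser_deflection=row.force_per_laser_deflection,
            loadpoint_per_laser_deflection=row.loadpoint_per_laser_deflection,
            source=source,
        )

    def wire(
        self,
        material: WireMaterial | str,
        diameter_um: float,
        tip: TipGeometry | str = TipGeometry.BLUNT,
        end_condition: float = 1.0,
    ) -> WireSpec:
        """WireSpec with the stock overhang for its diameter as unsupported length."""
        material = WireMaterial(material)
        mat = self._model.wires.materials.get(material.value)
        if mat is None:
            raise KeyError(f"no material data for '{material.value}'")
        key = str(int(diameter_um)) if float(diameter_um).is_integer() else str(diameter_um)
        overhang = self._model.wires.overhang_mm.get(key)
        if overhang is None:
            raise KeyError(f"no stock overhang for diameter {diameter_um} µm")
        return WireSpec.from_bench(
            material=material,
            elastic_modulus_gpa=mat.elastic_modulus_gpa,
            diameter_um=diameter_um,
            unsupported_length_mm=overhang,
            end_condition=end_condition,
            tip=TipGeometry(tip),
        )

    @property
    def wire_diameters_um(self) -> list[float]:
        return list(self._model.wires.diameters_um)


def load_registry(path: str | Path | None = None) -> SystemRegistry:
    """Load and validate a registry file; ``None`` loads the packaged default."""
    if path is None:
        text = resources.files("beamforce").joinpath("data/system.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return SystemRegistry(_SystemModel.model_validate(raw))


@lru_cache(maxsize=1)
def default_registry() -> SystemRegistry:
    """The packaged registry (cached; treat as read-only)."""
    return load_registry(None)
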