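"""Closed-form mechanics of the cantilever sensing beam and slender microwires.

The force sensor is a vertical cantilever beam clamped over its bottom
15 mm, with the microelectrode mounted on a top plate at the free end and a
laser displacement sensor reading the beam deflection ``d_c`` at a fixed
height.  Euler-Bernoulli theory for a point load at the free end gives the
two calibration ratios that turn a laser reading into a force and into the
load-point deflection:

* ``F_i / d_c`` — stiffness ratio seen by the laser (mN/mm),
* ``d_l / d_c`` — dimensionless amplification from laser point to load point.

All arms are measured from the top of the clamp: load arm ``a = l - clamp``
and laser arm ``x = c - clamp``.  For a tip load ``F`` the deflection at
station ``x <= a`` is ``F x^2 (3a - x) / (6 EI)``.

This module also covers the slender-column side of the problem: the Euler
critical buckling load that decides whether a microwire penetrates the
brain membranes or buckles, and the measurement error induced by beam tilt.

Internally everything is SI (m, N, Pa); public signatures use the bench
units stated in each docstring (mm, GPa, mN, µm, degrees).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

__all__ = [
    "BeamSpec",
    "LaserSpec",
    "CalibrationMap",
    "CalibrationSource",
    "WireSpec",
    "WireMaterial",
    "TipGeometry",
    "TiltResult",
    "flexural_rigidity",
    "ideal_force_ratio",
    "ideal_displacement_ratio",
    "ideal_calibration",
    "measurement_capacity",
    "tilt_error",
    "critical_buckling_load",
    "percent_difference",
]

_MM = 1e-3  # mm -> m
_UM = 1e-6  # µm -> m
_GPA = 1e9  # GPa -> Pa


class CalibrationSource(str, Enum):
    FEM = "fem"
    IDEAL = "ideal"
    EXPERIMENT = "experiment"


class WireMaterial(str, Enum):
    TUNGSTEN = "tungsten"
    STAINLESS_STEEL = "stainless_steel"
    OTHER = "other"


class TipGeometry(str, Enum):
    BLUNT = "blunt"
    SHARP = "sharp"


@dataclass(frozen=True)
class BeamSpec:
    """Geometry and material of one cantilever sensing beam.

    Parameters
    ----------
    name : str
        Identifier, e.g. ``"beam1"``.
    elastic_modulus : float
        Young's modulus ``E`` in Pa.
    length_from_base : float
        Beam length ``l`` from base to load point, in m.
    thickness : float
        Thickness ``h`` in the bending direction, in m.
    width : float
        Width ``b``, in m.
    clamp_height : float
        Height of the fixed clamp at the base, in m (15 mm on the bench).
    """

    name: str
    elastic_modulus: float
    length_from_base: float
    thickness: float
    width: float
    clamp_height: float = 15.0 * _MM

    def __post_init__(self) -> None:
        for field in ("elastic_modulus", "length_from_base", "thickness", "width", "clamp_height"):
            if getattr(self, field) <= 0:
                raise ValueError(f"BeamSpec.{field} must be strictly positive")
        if self.clamp_height >= self.length_from_base:
            raise ValueError("clamp_height must be below the load point")

    @classmethod
    def from_bench(
        cls,
        name: str,
        elastic_modulus_gpa: float,
        length_mm: float,
        thickness_mm: float,
        width_mm: float,
        clamp_height_mm: float = 15.0,
    ) -> "BeamSpec":
        """Build from the bench units (GPa, mm) used in lab records."""
        return cls(
            name=name,
            elastic_modulus=elastic_modulus_gpa * _GPA,
            length_from_base=length_mm * _MM,
            thickness=thickness_mm * _MM,
            width=width_mm * _MM,
            clamp_height=clamp_height_mm * _MM,
        )

    @property
    def load_arm(self) -> float:
        """Effective cantilever length ``a = l - clamp`` in m."""
        return self.length_from_base - self.clamp_height


@dataclass(frozen=True)
class LaserSpec:
    """Laser displacement sensor: mounting height, range and resolution.

    ``height_from_base`` is ``c`` in m; ``range`` in m; ``resolution`` in m
    (0.01 µm repeatability over a 2 mm range for the stock sensor).
    """

    height_from_base: float = 171.0 * _MM
    range: float = 2.0 * _MM
    resolution: float = 0.01 * _UM

    def __post_init__(self) -> None:
        if self.height_from_base <= 0:
            raise ValueError("laser height must be positive")
        if not (self.range > self.resolution > 0):
            raise ValueError("require range > resolution > 0")


@dataclass(frozen=True)
class CalibrationMap:
    """The two linear coefficients tying the laser reading to physics.

    ``force_per_laser_deflection`` is ``F_i/d_c`` in mN/mm;
    ``loadpoint_per_laser_deflection`` is the dimensionless ``d_l/d_c``.
    """

    force_per_laser_deflection: float
    loadpoint_per_laser_deflection: float
    source: CalibrationSource = CalibrationSource.FEM

    def __post_init__(self) -> None:
        if self.force_per_laser_deflection <= 0 or self.loadpoint_per_laser_deflection <= 0:
            raise ValueError("calibration ratios must be strictly positive")

    @property
    def beam_stiffness(self) -> float:
        """Beam stiffness at the load point, ``k_b = F_i/d_l`` in mN/mm."""
        return self.force_per_laser_deflection / self.loadpoint_per_laser_deflection


@dataclass(frozen=True)
class WireSpec:
    """A slender microwire (or shank) under axial insertion load.

    ``elastic_modulus`` in Pa, ``diameter`` in m, ``unsupported_length`` in m
    (the overhang out of the capillary tube), ``end_condition`` the
    dimensionless Euler factor ``m`` for the buckling mode.
    """

    material: WireMaterial
    elastic_modulus: float
    diameter: float
    unsupported_length: float
    end_condition: float = 1.0
    tip: TipGeometry = TipGeometry.BLUNT

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.unsupported_length <= 0 or self.end_condition <= 0:
            raise ValueError("wire diameter, unsupported length and end condition must be positive")
        if self.elastic_modulus <= 0:
            raise ValueError("wire elastic modulus must be positive")

    @classmethod
    def from_bench(
        cls,
        material: WireMaterial | str,
        elastic_modulus_gpa: float,
        diameter_um: float,
        unsupported_length_mm: float,
        end_condition: float = 1.0,
        tip: TipGeometry | str = TipGeometry.BLUNT,
    ) -> "WireSpec":
        return cls(
            material=WireMaterial(material),
            elastic_modulus=elastic_modulus_gpa * _GPA,
            diameter=diameter_um * _UM,
            unsupported_length=unsupported_length_mm * _MM,
            end_condition=end_condition,
            tip=TipGeometry(tip),
        )


@dataclass(frozen=True)
class TiltResult:
    """Beam-tilt measurement error: angle in degrees, relative error fraction."""

    angle: float
    relative_error: float


def flexural_rigidity(beam: BeamSpec) -> float:
    """Flexural rigidity ``EI = E b h^3 / 12`` of a rectangular beam, in N·m²."""
    return beam.elastic_modulus * beam.width * beam.thickness**3 / 12.0


def _arms(beam: BeamSpec, laser: LaserSpec) -> tuple[float, float]:
    a = beam.load_arm
    x = laser.height_from_base - beam.clamp_height
    if x <= 0:
        raise ValueError("laser must sit above the clamp")
    if x > a:
        raise ValueError("laser must sit at or below the load point")
    return a, x


def ideal_force_ratio(beam: BeamSpec, laser: LaserSpec) -> float:
    """Ideal-cantilever stiffness ratio ``F_i/d_c`` in mN/mm.

    Euler-Bernoulli deflection at the laser station under a tip point load:
    ``d_c = F x^2 (3a - x) / (6 EI)``, hence ``F/d_c = 6 EI / (x^2 (3a - x))``.
    The SI value in N/m equals the bench value in mN/mm.
    """
    a, x = _arms(beam, laser)
    return 6.0 * flexural_rigidity(beam) / (x**2 * (3.0 * a - x))


def ideal_displacement_ratio(beam: BeamSpec, laser: LaserSpec) -> float:
    """Ideal-cantilever deflection amplification ``d_l/d_c`` (dimensionless).

    Ratio of tip deflection ``F a^3 / 3EI`` to laser-station deflection,
    ``2 a^3 / (x^2 (3a - x))``; equals 1 when the laser sits at the tip.
    """
    a, x = _arms(beam, laser)
    return 2.0 * a**3 / (x**2 * (3.0 * a - x))


def ideal_calibration(beam: BeamSpec, laser: LaserSpec) -> CalibrationMap:
    """CalibrationMap from ideal-cantilever theory for this beam and laser."""
    return CalibrationMap(
        force_per_laser_deflection=ideal_force_ratio(beam, laser),
        loadpoint_per_laser_deflection=ideal_displacement_ratio(beam, laser),
        source=CalibrationSource.IDEAL,
    )


def measurement_capacity(calib: CalibrationMap, laser: LaserSpec) -> tuple[float, float]:
    """Measurement capacity of a beam/laser pairing.

    Returns ``(max_force, force_resolution)`` in (mN, µN): the force that
    drives the laser to full range, and the force step matching one laser
    resolution quantum.
    """
    ratio = calib.force_per_laser_deflection  # mN/mm
    max_force_mn = ratio * (laser.range / _MM)
    resolution_un = ratio * (laser.resolution / _MM) * 1e3  # mN -> µN
    return max_force_mn, resolution_un


def tilt_error(angle_deg: float) -> TiltResult:
    """Relative measurement error ``1 - cos(alpha)`` from beam tilt.

    The top plate tilts with the deflected beam; the load and displacement
    components along the insertion axis shrink by ``cos(alpha)``.
    Valid for ``0 <= alpha < 90`` degrees.
    """
    if not 0.0 <= angle_deg < 90.0:
        raise ValueError("tilt angle must be in [0, 90) degrees")
    return TiltResult(angle=angle_deg, relative_error=1.0 - math.cos(math.radians(angle_deg)))


def critical_buckling_load(wire: WireSpec) -> float:
    """Euler critical buckling load ``P = m pi^2 E I / L_U^2`` in mN.

    Circular cross-section: ``I = pi d^4 / 64``.  A wire penetrates the
    membrane only if the rupture force stays below this load.
    """
    second_moment = math.pi * wire.diameter**4 / 64.0
    load_n = (
        wire.end_condition
        * math.pi**2
        * wire.elastic_modulus
        * second_moment
        / wire.unsupported_length**2
    )
    return load_n * 1e3  # N -> mN


def rectangular_buckling_load(
    elastic_modulus: float, width: float, thickness: float, unsupported_length: float,
    end_condition: float = 1.0,
) -> float:
    """Euler load for a rectangular shank, ``I = w t^3 / 12`` (SI in, mN out)."""
    if min(elastic_modulus, width, thickness, unsupported_length, end_condition) <= 0:
        raise ValueError("all shank parameters must be positive")
    second_moment = width * thickness**3 / 12.0
    return end_condition * math.pi**2 * elastic_modulus * second_moment / unsupported_length**2 * 1e3


def percent_difference(value: float, reference: float) -> float:
    """``|value - reference| / reference × 100`` (percent) against a stated reference."""
    if reference == 0:
        raise ValueError("reference must be nonzero")
    return abs(value - reference) / abs(reference) * 100.0
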