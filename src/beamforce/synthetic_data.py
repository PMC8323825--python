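"""Synthetic insertion traces and factorial insertion studies.

No raw laser traces are deposited with the study, so everything downstream
is exercised on simulated data with the same structure the bench produces:

* a quasi-static series-spring contact phase — the sensing beam (stiffness
  ``k_b`` at the load point) and the membrane (linear spring ``k_m``) share
  the stage displacement, so the force ramps at ``k_eff = (1/k_b+1/k_m)^-1``
  times the feed;
* breathing of the anesthetized animal, modeled as sinusoidal motion of the
  brain surface (period 1–2 s) that modulates the contact force;
* sudden membrane rupture with beam rebound once the contact force reaches
  the membrane strength, then a shallow friction/cutting plateau;
* stage retraction ending in an adhesion dip below zero force;
* laser sensor noise and 0.01 µm quantization on the recorded ``d_c``.

The study generator draws whole factorial trial tables (material × tip ×
diameter × membrane) with a linear diameter effect, multiplicative tip and
membrane effects, and buckling whenever the latent rupture force exceeds
the wire's Euler critical load.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .beam_mechanics import BeamSpec, CalibrationMap, LaserSpec, critical_buckling_load
from .profile_pipeline import DisplacementTrace, Membrane
from .registry import SystemRegistry, default_registry

__all__ = [
    "MembraneModel",
    "PhysioNoise",
    "StudyDesign",
    "InsertionGroundTruth",
    "simulate_insertion",
    "simulate_study",
    "default_trial_counts",
]


@dataclass(frozen=True)
class MembraneModel:
    """Linear-elastic membrane up to rupture.

    stiffness : mN/mm resisting dimpling (series spring with the beam).
    rupture_force : mN at which the membrane tears (ground truth).
    post_rupture_friction_slope : mN per mm of insertion depth on the
        friction/cutting plateau.
    adhesion_force : mN pulled below zero at the end of retraction.
    """

    stiffness: float = 3.0
    rupture_force: float = 3.0
    post_rupture_friction_slope: float = 0.2
    adhesion_force: float = 0.3

    def __post_init__(self) -> None:
        if self.stiffness <= 0 or self.rupture_force <= 0:
            raise ValueError("membrane stiffness and rupture force must be positive")


@dataclass(frozen=True)
class PhysioNoise:
    """Physiologic and sensor noise riding on the laser reading.

    breathing_period : s; ``None`` draws uniformly from [1, 2] per trace.
    breathing_amplitude : mN, force-referred amplitude of the breathing
        oscillation.
    sensor_noise_sd : µm of Gaussian noise on ``d_c``.
    quantization : µm; laser readings snap to this grid (0 disables).
    """

    breathing_period: float | None = None
    breathing_amplitude: float = 0.05
    sensor_noise_sd: float = 0.05
    quantization: float = 0.01

    def __post_init__(self) -> None:
        if self.breathing_period is not None and self.breathing_period <= 0:
            raise ValueError("breathing period must be positive")
        if min(self.breathing_amplitude, self.sensor_noise_sd, self.quantization) < 0:
            raise ValueError("noise amplitudes must be nonnegative")


@dataclass(frozen=True)
class InsertionGroundTruth:
    """What the simulator actually did, for end-to-end recovery checks."""

    rupture_force: float
    rupture_index: int
    dimpling_at_rupture: float
    breathing_period: float
    breathing_amplitude: float
    effective_stiffness: float
    beam_stiffness: float
    membrane_stiffness: float
    feed_um_s: float
    truncated: bool
    seed: int | None


def simulate_insertion(
    beam: BeamSpec,
    calib: CalibrationMap,
    membrane: MembraneModel,
    noise: PhysioNoise = PhysioNoise(),
    feed: float = 100.0,
    seed: int | np.random.Generator | None = None,
    laser: LaserSpec = LaserSpec(),
    pre_contact_s: float = 2.0,
    post_rupture_s: float = 5.0,
    sample_period: float = 0.002,
) -> tuple[DisplacementTrace, InsertionGroundTruth]:
    """Simulate one insertion and return the raw trace plus ground truth.

    The contact force follows ``F = k_eff (d_t + b(t))`` (clipped at zero)
    with ``b`` the breathing motion, until it first reaches the membrane's
    rupture force; the beam then rebounds in one quasi-static step onto the
    friction plateau ``F = s·depth`` and the stage later retracts, sweeping
    through an adhesion dip.  The recorded channel is
    ``d_c = F / (F_i/d_c)`` plus sensor noise, quantized to the laser grid.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_val = None if isinstance(seed, np.random.Generator) else seed

    k_b = calib.beam_stiffness  # mN/mm
    k_m = membrane.stiffness
    k_eff = 1.0 / (1.0 / k_b + 1.0 / k_m)
    feed_mm_s = feed * 1e-3

    period = noise.breathing_period if noise.breathing_period is not None else rng.uniform(1.0, 2.0)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    amp_mm = noise.breathing_amplitude / k_eff  # force-referred -> surface motion

    # nominal rupture time plus margin for breathing to cross the threshold
    t_rupture_nominal = membrane.rupture_force / (k_eff * feed_mm_s)
    range_mm = laser.range / 1e-3
    force_ratio = calib.force_per_laser_deflection
    max_force = range_mm * force_ratio
    truncated = membrane.rupture_force > max_force
    t_ramp_end = min(t_rupture_nominal + 2.0 * period, max_force / (k_eff * feed_mm_s))

    n_pre = int(round(pre_contact_s / sample_period))
    n_ramp = int(np.ceil(t_ramp_end / sample_period)) + 1
    t_local = np.arange(n_ramp) * sample_period
    breathing = amp_mm * np.sin(2.0 * np.pi * t_local / period + phase)
    d_t_ramp = feed_mm_s * t_local
    f_ramp = np.clip(k_eff * (d_t_ramp + breathing), 0.0, None)

    crossing = np.nonzero(f_ramp >= membrane.rupture_force)[0]
    if crossing.size == 0:
        truncated = True
        rupture_local = n_ramp - 1
    else:
        rupture_local = int(crossing[0])

    force = [f_ramp[: rupture_local + 1]]
    s = membrane.post_rupture_friction_slope
    if not truncated:
        # post-rupture: quasi-static friction plateau with beam rebound
        n_post = int(round(post_rupture_s / sample_period))
        t_post = t_local[rupture_local] + np.arange(1, n_post + 1) * sample_period
        b_post = amp_mm * np.sin(2.0 * np.pi * t_post / period + phase)
        d_t_post = feed_mm_s * t_post
        f_post = np.clip(s * (d_t_post + b_post) / (1.0 + s / k_b), 0.0, None)
        force.append(f_post)

        # retraction: ramp down to the adhesion dip, then back to zero
        d_t_peak = d_t_post[-1]
        n_ret = int(round(d_t_peak / feed_mm_s / sample_period))
        f_start = f_post[-1]
        half = n_ret // 2
        f_ret = np.concatenate([
            np.linspace(f_start, -membrane.adhesion_force, half, endpoint=False),
            np.linspace(-membrane.adhesion_force, 0.0, n_ret - half),
        ])
        force.append(f_ret)
        retraction_index = n_pre + rupture_local + 1 + n_post
    else:
        retraction_index = None

    f_full = np.concatenate([np.zeros(n_pre), *force])
    d_c = f_full / force_ratio
    if noise.sensor_noise_sd > 0:
        d_c = d_c + rng.normal(0.0, noise.sensor_noise_sd * 1e-3, size=d_c.size)
    if noise.quantization > 0:
        q = noise.quantization * 1e-3
        d_c = np.round(d_c / q) * q
    d_c = np.minimum(d_c, range_mm)  # the sensor saturates at its range

    trace = DisplacementTrace(
        samples=d_c,
        sample_period=sample_period,
        insertion_rate=feed,
        start_index=n_pre,
        retraction_index=retraction_index,
        beam_name=beam.name,
    )
    truth = InsertionGroundTruth(
        rupture_force=membrane.rupture_force,
        rupture_index=n_pre + rupture_local,
        dimpling_at_rupture=membrane.rupture_force / k_m,
        breathing_period=period,
        breathing_amplitude=noise.breathing_amplitude,
        effective_stiffness=k_eff,
        beam_stiffness=k_b,
        membrane_stiffness=k_m,
        feed_um_s=feed,
        truncated=truncated,
        seed=seed_val,
    )
    return trace, truth


def default_trial_counts() -> list[tuple[str, str, float, Membrane, int]]:
    """The study's factorial layout: (material, tip, diameter µm, membrane, n).

    Eleven wire types (sharpening only for tungsten; 12 µm wires only blunt)
    over two membrane conditions; 12 µm wires are not attempted through the
    dura.  115 pia-only and 123 dura-pia trials.
    """
    pia, dura = Membrane.PIA_ONLY, Membrane.DURA_PIA
    w, ss = "tungsten", "stainless_steel"
    return [
        (w, "sharp", 25, pia, 11), (w, "sharp", 50, pia, 11), (w, "sharp", 100, pia, 10),
        (w, "blunt", 12, pia, 9), (w, "blunt", 25, pia, 11),
        (w, "blunt", 50, pia, 10), (w, "blunt", 100, pia, 11),
        (ss, "blunt", 12, pia, 11), (ss, "blunt", 25, pia, 10),
        (ss, "blunt", 50, pia, 11), (ss, "blunt", 100, pia, 10),
        (w, "sharp", 25, dura, 14), (w, "sharp", 50, dura, 14), (w, "sharp", 100, dura, 14),
        (w, "blunt", 25, dura, 14), (w, "blunt", 50, dura, 14), (w, "blunt", 100, dura, 12),
        (ss, "blunt", 25, dura, 14), (ss, "blunt", 50, dura, 14), (ss, "blunt", 100, dura, 13),
    ]


@dataclass(frozen=True)
class StudyDesign:
    """Generative model of a whole factorial insertion study.

    The latent rupture force of one trial is

    ``(intercept + slope · diameter) · tip_mult · membrane_mult · material_factor
      + membrane_mult · (animal effect + residual)``

    and the dimpling depth is the force divided by the membrane stiffness
    plus its own measurement noise.  A trial buckles (no rupture force or
    dimpling recorded) when its latent rupture force exceeds the wire's
    Euler critical load.
    """

    trial_counts: list[tuple[str, str, float, Membrane, int]] = field(
        default_factory=default_trial_counts
    )
    n_animals: int = 8
    intercept_mn: float = 0.2
    slope_mn_per_um: float = 0.028
    sharp_tip_multiplier: float = 0.6
    membrane_multiplier: dict = field(
        default_factory=lambda: {Membrane.PIA_ONLY: 1.0, Membrane.DURA_PIA: 15.0}
    )
    material_factor: dict = field(
        default_factory=lambda: {"tungsten": 1.0, "stainless_steel": 1.0}
    )
    membrane_stiffness: dict = field(
        default_factory=lambda: {Membrane.PIA_ONLY: 3.0, Membrane.DURA_PIA: 18.0}
    )
    animal_sd: float = 0.0
    residual_sd: float = 0.3
    dimpling_noise_sd_mm: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.trial_counts:
            raise ValueError("study design has no trials")
        if any(n < 1 for *_, n in self.trial_counts):
            raise ValueError("replicates must be >= 1")
        if self.sharp_tip_multiplier <= 0 or any(v <= 0 for v in self.membrane_multiplier.values()):
            raise ValueError("effect multipliers must be positive")


def simulate_study(
    design: StudyDesign = StudyDesign(),
    seed: int | np.random.Generator | None = None,
    registry: SystemRegistry | None = None,
) -> pd.DataFrame:
    """Draw one study table from the design's generative model.

    Returns a DataFrame with columns material, tip, diameter_um, membrane,
    outcome, rupture_force_mn, dimpling_mm, animal, order.  Identical seeds
    give identical tables.
    """
    if seed is None:
        seed = design.seed
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    registry = registry or default_registry()

    animal_effects = rng.normal(0.0, design.animal_sd, size=design.n_animals)
    rows = []
    for material, tip, diameter, membrane, n in design.trial_counts:
        mem_mult = design.membrane_multiplier[membrane]
        mean = (
            (design.intercept_mn + design.slope_mn_per_um * diameter)
            * (design.sharp_tip_multiplier if tip == "sharp" else 1.0)
            * mem_mult
            * design.material_factor[material]
        )
        wire = registry.wire(material, diameter, tip)
        euler = critical_buckling_load(wire)
        animals = rng.integers(0, design.n_animals, size=n)
        latent = mean + mem_mult * (
            animal_effects[animals] + rng.normal(0.0, design.residual_sd, size=n)
        )
        latent = np.clip(latent, 0.01, None)
        dimpling = latent / design.membrane_stiffness[membrane] + rng.normal(
            0.0, design.dimpling_noise_sd_mm, size=n
        )
        dimpling = np.clip(dimpling, 0.0, None)
        for i in range(n):
            buckled = latent[i] > euler
            rows.append(
                {
                    "material": material,
                    "tip": tip,
                    "diameter_um": diameter,
                    "membrane": membrane.value,
                    "outcome": "buckled" if buckled else "penetrated",
                    "rupture_force_mn": np.nan if buckled else latent[i],
                    "dimpling_mm": np.nan if buckled else dimpling[i],
                    "animal": int(animals[i]),
                }
            )

    table = pd.DataFrame(rows)
    # randomized insertion order within each hemisphere (membrane condition)
    order = np.empty(len(table), dtype=int)
    for _, idx in table.groupby("membrane").groups.items():
        order[np.asarray(idx)] = rng.permutation(len(idx))
    table["order"] = order
    return table
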