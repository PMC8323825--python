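#!/usr/bin/env python
"""Calibration mechanics of the four sensing beams.

Computes each beam's flexural rigidity, compares the ideal-cantilever
force/deflection ratios with the FEM and bench calibration coefficients,
derives the force range and resolution of each beam/laser pairing, and
tabulates the tilt-induced measurement error at the worst-case angles.

Writes results/calibration/{coefficients,capacity,tilt_error}.csv.
"""

from pathlib import Path

import pandas as pd

from beamforce.beam_mechanics import (
    flexural_rigidity,
    ideal_displacement_ratio,
    ideal_force_ratio,
    measurement_capacity,
    percent_difference,
    tilt_error,
)
from beamforce.registry import default_registry

OUT = Path(__file__).resolve().parents[1] / "results" / "calibration"
OUT.mkdir(parents=True, exist_ok=True)

registry = default_registry()
laser = registry.laser

rows, capacity_rows = [], []
for name in registry.beam_names:
    beam = registry.beam(name)
    fem = registry.calibration(name, "fem")
    exp = registry.calibration(name, "experiment")
    ideal_f = ideal_force_ratio(beam, laser)
    ideal_d = ideal_displacement_ratio(beam, laser)
    rows.append(
        dict(
            beam=name,
            EI_Nm2=round(flexural_rigidity(beam), 4),
            ideal_F_dc=round(ideal_f, 3),
            fem_F_dc=fem.force_per_laser_deflection,
            diff_pct=round(percent_difference(fem.force_per_laser_deflection, ideal_f), 2),
            ideal_dl_dc=round(ideal_d, 4),
            fem_dl_dc=fem.loadpoint_per_laser_deflection,
            exp_dl_dc=exp.loadpoint_per_laser_deflection,
            disc_pct=round(
                percent_difference(fem.loadpoint_per_laser_deflection,
                                   exp.loadpoint_per_laser_deflection), 2
            ),
        )
    )
    max_force, resolution = measurement_capacity(fem, laser)
    capacity_rows.append(
        dict(beam=name, max_force_mn=round(max_force, 2), resolution_un=round(resolution, 3))
    )

coeffs = pd.DataFrame(rows)
capacity = pd.DataFrame(capacity_rows)
coeffs.to_csv(OUT / "coefficients.csv", index=False)
capacity.to_csv(OUT / "capacity.csv", index=False)

# worst-case tilt at rupture for each beam (angles from the deflection model)
tilt = pd.DataFrame(
    [dict(beam=b, angle_deg=a, error_pct=round(tilt_error(a).relative_error * 100, 3))
     for b, a in [("beam1", 0.92), ("beam2", 1.25), ("beam3", 1.75), ("beam4", 1.22)]]
)
tilt.to_csv(OUT / "tilt_error.csv", index=False)

print("Calibration coefficients (F/d_c in mN/mm):")
print(coeffs.to_string(index=False))
no_b2 = coeffs[coeffs.beam != "beam2"]
print("\nGravity on the highly flexible beams drives the FEM force "
      "coefficients away from the ideal-cantilever values by up to "
      f"{no_b2.diff_pct.max():.2f}% (softest beam), while the bench d_l/d_c "
      f"matches FEM within {coeffs.disc_pct.max():.2f}%. Beam2's published "
      "ideal force ratio disagrees with Euler-Bernoulli theory for its own "
      "geometry (see docs/methods.md); its computed row here uses the theory "
      "value.")
print("\nMeasurement capacity per beam:")
print(capacity.to_string(index=False))
print(f"\nThe softest beam resolves {capacity.resolution_un.min():.3f} µN over "
      f"{capacity.max_force_mn.min():.1f} mN; the stiffest reaches "
      f"{capacity.max_force_mn.max():.0f} mN at {capacity.resolution_un.max():.2f} µN.")
print("\nTilt-induced error stays below 0.05% at worst-case rupture loads:")
print(tilt.to_string(index=False))
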