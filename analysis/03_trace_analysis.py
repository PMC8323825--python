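#!/usr/bin/env python
"""Per-trace analysis: rupture recovery against simulator ground truth.

Reads the traces written by 02_simulate_insertions.py, converts each to
force/dimpling channels, detects the rupture drop, extracts the breathing
oscillation, and compares everything with the simulator's ground truth.
Also verifies that rupture-free (truncated) traces produce no false
detections.  Writes results/trace_analysis/recovery.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from beamforce.profile_pipeline import convert_trace, detect_rupture, extract_breathing, read_trace
from beamforce.registry import default_registry
from beamforce.synthetic_data import MembraneModel, PhysioNoise, simulate_insertion

SEED = 2026
ROOT = Path(__file__).resolve().parents[1] / "results"
SIM = ROOT / "simulation"
OUT = ROOT / "trace_analysis"
OUT.mkdir(parents=True, exist_ok=True)

if not (SIM / "ground_truth.csv").exists():
    raise SystemExit("run analysis/02_simulate_insertions.py first")

registry = default_registry()
calib = registry.calibration("beam1", "fem")
truth_table = pd.read_csv(SIM / "ground_truth.csv").set_index("trace")

rows = []
for path in sorted((SIM / "traces").glob("trace_*.csv")):
    truth = truth_table.loc[path.name]
    profile = convert_trace(read_trace(path), calib, laser=registry.laser)
    event = detect_rupture(profile)
    breathing = extract_breathing(profile)
    rows.append(
        dict(
            trace=path.name,
            true_force_mn=truth.rupture_force,
            detected_force_mn=event.rupture_force if event else np.nan,
            force_error_mn=abs(event.rupture_force - truth.rupture_force) if event else np.nan,
            true_dimpling_mm=truth.dimpling_at_rupture,
            detected_dimpling_mm=event.dimpling_at_rupture if event else np.nan,
            true_period_s=truth.breathing_period,
            detected_period_s=breathing.period if breathing else np.nan,
        )
    )
recovery = pd.DataFrame(rows)
recovery.to_csv(OUT / "recovery.csv", index=False)

# rupture-free control: membrane too strong to rupture within the range
false_positives = 0
beam = registry.beam("beam1")
for seed in range(50):
    trace, _ = simulate_insertion(
        beam, calib, MembraneModel(stiffness=3.0, rupture_force=100.0),
        PhysioNoise(), seed=SEED + seed, laser=registry.laser,
    )
    if detect_rupture(convert_trace(trace, calib)) is not None:
        false_positives += 1

mae = recovery.force_error_mn.mean()
period_err = (recovery.detected_period_s - recovery.true_period_s).abs().max()
print(f"Rupture detected in {recovery.detected_force_mn.notna().sum()}/{len(recovery)} traces.")
print(f"Rupture-force mean absolute error: {mae:.4f} mN "
      f"(breathing amplitude 0.05 mN; quantization-referred force "
      f"{0.01e-3 * calib.force_per_laser_deflection:.5f} mN).")
print(f"Breathing period recovered within {period_err:.3f} s on every trace.")
print(f"False positives on 50 rupture-free traces: {false_positives}.")
print(f"Table in {OUT / 'recovery.csv'}")
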