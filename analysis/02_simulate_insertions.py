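#!/usr/bin/env python
"""Simulate the study's raw material: insertion traces and the trial table.

Generates a batch of laser-displacement traces on the softest sensing beam
(membrane spring in series with the beam, breathing, sensor noise and
quantization) plus one full factorial study table, and stores both under
results/simulation/ in the same delimited-text formats the analysis
stages read.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from beamforce.profile_pipeline import write_trace
from beamforce.registry import default_registry
from beamforce.synthetic_data import (
    MembraneModel,
    PhysioNoise,
    StudyDesign,
    simulate_insertion,
    simulate_study,
)

SEED = 2026
N_TRACES = 20

OUT = Path(__file__).resolve().parents[1] / "results" / "simulation"
(OUT / "traces").mkdir(parents=True, exist_ok=True)

registry = default_registry()
beam = registry.beam("beam1")
calib = registry.calibration("beam1", "fem")
rng = np.random.default_rng(SEED)

membrane = MembraneModel(stiffness=3.0, rupture_force=3.0)
noise = PhysioNoise()  # breathing U[1,2] s / 0.05 mN; sensor 0.05 µm; 0.01 µm grid

truths = []
for i in range(N_TRACES):
    sub_seed = int(rng.integers(0, 2**31 - 1))
    trace, truth = simulate_insertion(
        beam, calib, membrane, noise, seed=sub_seed, laser=registry.laser
    )
    write_trace(OUT / "traces" / f"trace_{i:03d}.csv", trace)
    truths.append({"trace": f"trace_{i:03d}.csv", **vars(truth)})

truth_table = pd.DataFrame(truths)
truth_table.to_csv(OUT / "ground_truth.csv", index=False)

study = simulate_study(StudyDesign(), seed=SEED, registry=registry)
study.to_csv(OUT / "study.csv", index=False)

print(f"Simulated {N_TRACES} insertion traces on beam1 "
      f"(membrane 3 mN/mm, rupture 3 mN, feed 100 µm/s at 500 Hz).")
print(f"Breathing periods span {truth_table.breathing_period.min():.2f}–"
      f"{truth_table.breathing_period.max():.2f} s.")
print(f"\nSimulated factorial study: {len(study)} trials "
      f"({(study.membrane == 'pia_only').sum()} pia-only, "
      f"{(study.membrane == 'dura_pia').sum()} dura-pia), "
      f"{(study.outcome == 'buckled').sum()} buckled.")
print(f"Artifacts in {OUT}")
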