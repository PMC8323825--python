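#!/usr/bin/env python
"""Study-level statistics on the simulated factorial insertion study.

Reads the trial table written by 02_simulate_insertions.py and runs the
full statistical battery: buckling-rate table, diameter-linearity fits
(with the diameter² alternative), three-factor Type II ANOVA per response
and membrane, rupture/dimpling Pearson correlations per stratum, and the
dimpling-to-rupture-force ratio summary.  Report tables and trend plots go
to results/study_statistics/.
"""

from pathlib import Path

import pandas as pd

from beamforce.insertion_stats import build_report, read_study

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "study_statistics"

if not (ROOT / "simulation" / "study.csv").exists():
    raise SystemExit("run analysis/02_simulate_insertions.py first")

study = read_study(ROOT / "simulation" / "study.csv")
report = build_report(study, outdir=OUT)

buckling = report["buckling"]
pooled = buckling[buckling["pooled"]].set_index("membrane")["buckling_rate_pct"]
print(f"Study of {report['n_trials']} trials.")
print("Pooled buckling rates: "
      + ", ".join(f"{m}: {v:.1f}%" for m, v in pooled.items()))

print("\nDiameter-linearity fits (per-condition means):")
for fit in report["fits"]:
    print(f"  [{fit.membrane}] {fit.response}: slope {fit.slope:.4f}, "
          f"R² {fit.r_squared:.3f} (diameter² alternative R² "
          f"{fit.quadratic_r_squared:.3f})")

print("\nThree-factor ANOVA (Type II, main effects):")
for res in report["anovas"]:
    line = ", ".join(
        f"{factor} F={res.f(factor):.2f} p={res.p(factor):.3g}"
        for factor in ("material", "tip", "diameter_um")
    )
    print(f"  [{res.membrane}] {res.response}: {line}")

print("\nRupture force vs dimpling depth (Pearson):")
corr = pd.DataFrame([vars(c) for c in report["correlations"]])
print(corr.to_string(index=False))
print(f"\nTables and plots in {OUT}")
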