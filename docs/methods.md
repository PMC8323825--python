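# Methods

`beamforce` models a cantilever-beam force/dimpling measurement system for
microelectrode insertion into the brain of an anesthetized rat, and the
statistical analyses run on the insertion trials it records. This note
documents the models, the defaults and why they were chosen, and what the
synthetic data do and do not establish.

## Sensing-beam mechanics

The force sensor is a thin vertical aluminum cantilever clamped over its
bottom 15 mm, with the microelectrode mounted on a top plate at the free
end and a laser displacement sensor (0.01 µm repeatability, 2 mm range)
reading the beam deflection `d_c` at height `c = 171 mm`. Four beams of
different thickness/width cover force ranges from ~6.5 mN (0.032 µN
resolution) to ~219 mN (1.09 µN resolution).

With a point load `F` at the free end, Euler–Bernoulli theory for a
cantilever of rigidity `EI = E b h³ / 12` gives the deflection at station
`x` as `F x² (3a − x) / 6EI`, where both arms are measured from the top of
the clamp: load arm `a = l − 15 mm`, laser arm `x = c − 15 mm`. This
clamp-subtraction convention is a modeling choice: it is the only
convention under which the closed forms reproduce the instrument
datasheet's ideal-cantilever coefficients for beams 1, 3 and 4 (verified
numerically), and it matches the physical boundary condition — the beam
cannot bend inside the clamp. The two calibration ratios are

* `F_i/d_c = 6EI / (x²(3a − x))` (mN/mm), and
* `d_l/d_c = 2a³ / (x²(3a − x))` (dimensionless, ≥ 1 for a laser below
  the load point).

Both are verified against an independent numerical double integration of
the curvature `M(s)/EI` to 6 significant figures.

Because the beams are extremely compliant, the weight of the top plate and
capillary tube matters: finite-element calibration of the instrumented
beams (consumed here as constants in the packaged registry, not
recomputed) differs from the ideal forms by up to ~20% on the softest
beam. The FEM `d_l/d_c` ratios agree with bench calibration within 2.4%.
No gravity-loaded beam model is attempted here; the FEM coefficients are
data.

**Known datasheet anomaly.** The published ideal-cantilever `F_i/d_c` for
beam 2 (16.62 mN/mm) is inconsistent with Euler–Bernoulli theory for beam
2's own geometry (the theory gives ≈ 7.94 mN/mm; beam 2's `d_l/d_c` *is*
consistent with theory). This looks like a transcription error in the
source material. Beam 2's ideal force ratio is therefore excluded from the
closed-form verification set; its FEM/bench coefficients are unaffected.

Beam tilt under deflection shrinks the measured force/displacement
components by `cos α`; the relative error `1 − cos α` stays below 0.05%
for the worst-case rupture loads (`α < 2°`), so tilt is reported, not
corrected.

## Wire buckling

A microwire penetrates the membrane only if the rupture force stays below
its Euler critical load `P = m π² E I / L_U²` with `I = π d⁴ / 64`
(circular section; a rectangular `w t³/12` variant covers silicon shanks).
Moduli: 410 GPa (tungsten), 200 GPa (AISI 304). The end-condition factor
`m` depends on the buckling mode of the actual insertion constraint and is
not identifiable from the data; it is exposed as a parameter with default
1 (pinned–pinned), the conventional conservative choice. Unsupported
lengths default to the stock overhangs: 1.5 mm (12/25 µm wires), 3.0 mm
(50/100 µm).

## Trace pipeline

Traces are `d_c` at 500 Hz. Conversion is linear: `F_i = (F_i/d_c)·d_c`,
`d_l = (d_l/d_c)·d_c`; the stage channel `d_t` ramps at the feed rate
(100 µm/s) from first contact and reverses at retraction; dimpling is the
identity `d_i = d_t − d_l`, which holds channel-wise by construction.
Readings at the laser range are flagged as saturated, never clipped
silently.

**Rupture detection.** Rupture is a sudden force drop off a fresh running
maximum. The detector triggers at the first sample that (i) sits at the
running maximum and (ii) is followed within `drop_window_s = 0.1 s` by a
fall of at least `max(drop_fraction · max, min_drop_mn)` with
`drop_fraction = 0.05` and `min_drop_mn = 0.2 mN`. The short window
separates rupture from breathing (1–2 s period): off a breathing crest the
force can fall by at most `A(1 − cos(2π·0.1/T)) ≈ 0.2 A` in 0.1 s, far
below the absolute floor for physiologic amplitudes. The absolute floor
exists because early in the ramp the running maximum is small and a purely
relative criterion would fire on breathing; 0.2 mN is well below pia
rupture forces (~0.5–3 mN) and far above breathing amplitudes (~0.05 mN).
The rupture force is read at the pre-drop running maximum (the crest
inside the triggering window) and dimpling at that same sample.

**Outcome classification.** Penetrated ⇔ a rupture event exists. With no
drop, a trace is called buckled when the force plateaus (fitted slope
below 0.05 mN/s over the trailing 2 s) at a level within 30% of the wire's
Euler load — the force a buckled column sustains. This plateau-near-Euler
criterion is this package's construction; the study's own buckled/
penetrated labels were assigned at the bench, and no algorithmic rule for
them is on record. Anything else is invalid, with a diagnostic.

**Breathing extraction.** The pre-rupture force segment (≥ 4 s) is
linearly detrended; the coarse spectral peak of the periodogram in the
0.2–5 Hz band is refined by harmonic least squares on a frequency grid one
bin wide, which removes leakage scalloping and recovers both period
(±0.1 s) and amplitude (±10%) on simulated traces.

## Synthetic traces

No real traces are deposited, so the simulator is the test bed. It
emulates:

* **series-spring contact**: beam stiffness at the load point
  `k_b = (F_i/d_c)/(d_l/d_c)` in series with a linear membrane spring
  `k_m`, so the force ramps at `k_eff = (1/k_b + 1/k_m)⁻¹` times the feed.
  A linear membrane is consistent with the observed linear dimpling rise;
  no hyperelastic model is attempted. Pre-rupture the spring balance
  `k_b d_l = k_m d_i` holds exactly in noiseless traces.
* **breathing** as sinusoidal brain-surface motion (period uniform in
  [1, 2] s, force-referred amplitude default 0.05 mN) added to the stage
  displacement, so the *contact force itself* oscillates and rupture
  triggers when the true contact force reaches the membrane strength;
* **rupture** as an instantaneous drop with single-step quasi-static
  re-equilibration of the rebounding beam onto a friction/cutting plateau
  `F = s·depth` (default `s = 0.2` mN/mm) — the released beam deflection
  advances the wire;
* **retraction** ramping down through an adhesion dip (default 0.3 mN
  below zero) back to rest;
* **sensor artifacts**: Gaussian noise (0.05 µm sd) and 0.01 µm
  quantization on `d_c`, with saturation at the 2 mm range.

Membrane defaults — stiffness 3 mN/mm (pia) — put rupture dimpling around
1 mm for a 3 mN rupture, matching the qualitative scale of in vivo pia
dimpling. The membrane strength is a free parameter of each simulation;
no published per-trial values exist to calibrate against.

What the simulator does *not* model: viscoelastic/rate-dependent tissue
(the study used a single 100 µm/s feed), cardiac pulsation, blood-vessel
heterogeneity, friction build-up during deep insertion, and the dynamics
of the beam's post-rupture ring-down. Passing recovery tests therefore
demonstrates the pipeline's correctness under its stated assumptions, not
its performance on arbitrary in vivo traces.

## Synthetic studies

The study generator draws whole factorial trial tables in the study's own
layout: 11 wire types (tungsten sharp/blunt and stainless blunt; 12 µm
wires only blunt) over pia-only (115 trials) and dura-pia (123 trials; no
12 µm). Latent rupture force:

```
F = (b₀ + b₁·d) · tip_mult · mem_mult · mat_factor
    + mem_mult · (animal + residual)
```

Defaults: `b₀ = 0.2 mN`, `b₁ = 0.028 mN/µm` (pia forces ~0.5–3 mN across
12–100 µm), `tip_mult = 0.6` for sharp tips (sharpening reduces rupture
force by ~40%), `mem_mult = 15` for dura-pia (an order of magnitude above
pia), `mat_factor = 1` for both metals — the material-null default mirrors
the finding that wire material does not affect rupture force, and makes
the generator its own type-I-error calibration rig. Residual sd 0.3 mN
scales with the membrane multiplier. Dimpling is force divided by the
membrane stiffness (3 mN/mm pia, 18 mN/mm dura-pia — giving dura dimpling
~2.5× pia at ~15× the force) plus 0.05 mm of measurement noise. A trial
buckles, with no recorded force or dimpling, when its latent force exceeds
the wire's Euler load.

Per-animal random effects default to sd 0: the plain three-factor ANOVA
applied downstream assumes independent residuals, and the generator's
stated null-calibration property (material rejection rate ≈ α) holds only
under that assumption. Setting `animal_sd > 0` induces block correlation
that the fixed-effects ANOVA ignores, making its F-tests conservative for
within-animal-balanced factors; the parameter exists to explore exactly
that.

## Statistics

* **Buckling rates**: buckled cases as a percentage of all trials per
  condition, with pooled rows per membrane.
* **Diameter linearity**: OLS of per-condition *mean* response on
  diameter (fitting averages, as the study's trend plots do), with a
  parallel fit on diameter² for model comparison; raw-trial fits are an
  option. Fits can be restricted to one wire family (material × tip), which
  is how slope-recovery experiments are scored.
* **ANOVA**: main-effects (material + tip + diameter-as-categorical) on
  penetrated trials, Type II sums of squares. Type II is the standard
  choice for an unbalanced main-effects-only design; the original
  analysis's software and sum-of-squares type are unrecorded, so exact
  F-value reproduction is out of scope (the raw trials were never
  deposited). Two-sided p, α = 0.05.
* **Correlation**: Pearson r between rupture force and dimpling per
  stratum (all / sharp / blunt / each diameter; the 12 µm dura stratum
  does not exist by design). Strong: p < 0.05 and |r| > 0.7; moderate:
  0.3 < |r| < 0.7. Strata with n < 3 report an undefined p; constant
  vectors an undefined r.
* **Dimpling-to-force ratio**: mm/mN per penetrated trial; in noiseless
  synthetic data the ratio is exactly `1/k_m`.

## Problem sizes and numerical choices

Monte-Carlo suite sizes: 200 + 200 traces for rupture-recovery/false-
positive checks, 1000 studies for ANOVA type-I calibration, 100 studies
for slope recovery and linear-vs-quadratic comparison — large enough that
binomial error on a 5% rate is ~±0.7% and slope-mean error ~0.1%, small
enough to run routinely. The numerical beam oracle integrates curvature on
a 20001-point grid (trapezoid; exact for the linear curvature, O(h²) for
the second integral, relative error ~1e-9). Derived per-trace seeds stay
below 2³¹. All randomness flows through one `numpy` generator per entry
point; identical seeds give bit-identical traces and tables.

## Known limitations

* FEM calibration coefficients are constants; the package cannot
  recalibrate a modified instrument without new FEM/bench input.
* The buckling classifier depends on a correct Euler load, hence on the
  end-condition factor `m` the user supplies.
* Study-level statistics reproduce the *procedures*, not the published
  F/p/r values, which require the undeposited raw trials.
* The trace simulator's post-rupture and retraction segments are
  qualitative scaffolding for detector testing, not a tissue model.
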