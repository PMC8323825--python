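# Instrument registry: cantilever sensing beams, laser displacement sensor,
# calibration coefficient maps, and microwire stock used in the insertion study.
# Units follow the bench convention: lengths mm, moduli GPa, ratios mN/mm,
# laser resolution um, wire diameters um.

laser:
  height_from_base_mm: 171.0
  range_mm: 2.0
  resolution_um: 0.01

clamp_height_mm: 15.0

beams:
  beam1:
    material: Al-2024
    elastic_modulus_gpa: 73.1
    length_mm: 375.0
    thickness_mm: 0.5
    width_mm: 20.0
  beam2:
    material: Al-2024
    elastic_modulus_gpa: 73.1
    length_mm: 375.0
    thickness_mm: 0.625
    width_mm: 20.0
  beam3:
    material: Al-2024
    elastic_modulus_gpa: 73.1
    length_mm: 380.0
    thickness_mm: 0.8
    width_mm: 40.0
  beam4:
    material: Al-6061
    elastic_modulus_gpa: 68.9
    length_mm: 380.0
    thickness_mm: 1.5
    width_mm: 20.0

# Finite-element and bench calibration coefficients for each beam:
# force_per_laser_deflection (F_i/d_c, mN/mm) and the dimensionless
# load-point-to-laser deflection ratio (d_l/d_c).
calibration:
  fem:
    beam1: {force_per_laser_deflection: 3.238, loadpoint_per_laser_deflection: 4.1789}
    beam2: {force_per_laser_deflection: 15.648, loadpoint_per_laser_deflection: 4.1754}
    beam3: {force_per_laser_deflection: 31.226, loadpoint_per_laser_deflection: 4.3124}
    beam4: {force_per_laser_deflection: 109.36, loadpoint_per_laser_deflection: 4.2812}
  experiment:
    # Bench calibration measured only the deflection ratio (no uN-accurate
    # force reference exists at this range); force ratios mirror the FEM.
    beam1: {force_per_laser_deflection: 3.238, loadpoint_per_laser_deflection: 4.2816}
    beam2: {force_per_laser_deflection: 15.648, loadpoint_per_laser_deflection: 4.2544}
    beam3: {force_per_laser_deflection: 31.226, loadpoint_per_laser_deflection: 4.3999}
    beam4: {force_per_laser_deflection: 109.36, loadpoint_per_laser_deflection: 4.3775}
  # Ideal-cantilever (Euler-Bernoulli) coefficients are computed from beam
  # geometry at load time rather than stored.

wires:
  materials:
    tungsten: {elastic_modulus_gpa: 410.0}
    stainless_steel: {elastic_modulus_gpa: 200.0}
  # Overhang out of the capillary tube = unsupported length during insertion.
  overhang_mm:
    "12": 1.5
    "25": 1.5
    "50": 3.0
    "100": 3.0
  diameters_um: [12, 25, 50, 100]
  tip_geometries: [blunt, sharp]
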