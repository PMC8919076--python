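# Reference resting conditions for a 70 kg adult.
# Hemodynamic targets, wall volumes, branch target flows and the aortic
# orifice area follow the reference input table of the model; remaining
# constants are calibrated package defaults (docs/methods.md).
general:
  hr_bpm: 71.0
  co_l_min: 5.1
  map_mmhg: 91.0
  systolic_duration_frac: 0.41
walls:
  lv_wall_volume: 108.0
  septal_wall_volume: 45.0
  rv_wall_volume: 39.0
coronary_targets:
  RCA: {q0_ml_min: 112.0, endo_epi_ratio: 1.11}
  LAD: {q0_ml_min: 83.0, endo_epi_ratio: 1.11}
  LCx: {q0_ml_min: 60.0, endo_epi_ratio: 1.11}
territory_table:
  LCx: {RV: 0.0, S: 0.0, LV: 0.42}
  LAD: {RV: 0.0, S: 0.60, LV: 0.33}
  RCA: {RV: 1.0, S: 0.40, LV: 0.25}
valves:
  aortic: {area_cm2: 4.8, l_eff_cm: 10.0}
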