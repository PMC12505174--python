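# Subtype-conditioned phantom presets for the 7 glomerulopathy classes.
#
# SYNTHETIC calibration values: the distributions encode textbook
# ultrastructural tendencies (thin GBM in TBMN; thickened GBM in MN and DN;
# diffuse foot-process effacement in MCD and MN; electron-dense deposits in
# immune-mediated disease) but the numbers are generator choices for phantom
# benchmarking, not measurements from any patient cohort.
version: 1
common:
  nm_per_pixel: 8.0
  image_height: 224
  image_width: 768
  waviness_amplitude_px: [8.0, 18.0]
  waviness_period_px: [250.0, 450.0]
  boundary_noise_sd_px: 0.5
  reference_density_per_um: 5.0
  min_thickness_nm: 120.0
  max_thickness_nm: 900.0
subtypes:
  MCD:
    thickness_nm: {mean: 340.0, sd: 25.0}
    effaced_fraction: {mean: 0.88, sd: 0.04}
    edd_prob: 0.0
    edd_count: {mean: 0.0, sd: 0.0}
    edd_area_nm2: {mean: 20000.0, sd: 4000.0}
  MN:
    thickness_nm: {mean: 640.0, sd: 40.0}
    effaced_fraction: {mean: 0.85, sd: 0.05}
    edd_prob: 1.0
    edd_count: {mean: 8.0, sd: 1.5}
    edd_area_nm2: {mean: 25000.0, sd: 5000.0}
  IgA:
    thickness_nm: {mean: 360.0, sd: 25.0}
    effaced_fraction: {mean: 0.20, sd: 0.05}
    edd_prob: 1.0
    edd_count: {mean: 6.0, sd: 1.0}
    edd_area_nm2: {mean: 30000.0, sd: 6000.0}
  LN:
    thickness_nm: {mean: 440.0, sd: 30.0}
    effaced_fraction: {mean: 0.42, sd: 0.05}
    edd_prob: 1.0
    edd_count: {mean: 12.0, sd: 2.0}
    edd_area_nm2: {mean: 40000.0, sd: 8000.0}
  DN:
    thickness_nm: {mean: 780.0, sd: 40.0}
    effaced_fraction: {mean: 0.15, sd: 0.05}
    edd_prob: 0.0
    edd_count: {mean: 0.0, sd: 0.0}
    edd_area_nm2: {mean: 20000.0, sd: 4000.0}
  MsPGN:
    thickness_nm: {mean: 320.0, sd: 20.0}
    effaced_fraction: {mean: 0.08, sd: 0.03}
    edd_prob: 1.0
    edd_count: {mean: 3.0, sd: 1.0}
    edd_area_nm2: {mean: 15000.0, sd: 4000.0}
  TBMN:
    thickness_nm: {mean: 200.0, sd: 15.0}
    effaced_fraction: {mean: 0.04, sd: 0.02}
    edd_prob: 0.0
    edd_count: {mean: 0.0, sd: 0.0}
    edd_area_nm2: {mean: 20000.0, sd: 4000.0}
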