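# Default configuration of the simulated paired-device cohort run.
# Keys mirror mcht.pipeline.RunConfig.

geometry:
  azimuth_min_deg: -24.0
  azimuth_max_deg: 24.0
  elevation_max_deg: 48.0
  row_spacing_deg: 12.0
  column_azimuths_deg: [-24.0, -18.0, -12.0, -6.0, 0.0, 6.0, 12.0, 18.0, 24.0]
  pixels_per_degree: 15.0
  stop_threshold_px: 10

noise:
  false_positive_rate: 0.0
  false_negative_rate: 0.0
  slope_deg: 0.0

# Cohort strata (severe / mild / normal eyes)
n_severe: 18
n_mild: 6
n_normal: 6

tape_lift_mm: 2.5
forehead_bar_lift_mm: 0.0

# Synthesized central-field grid
baseline_db: 33.0
ecc_slope_db_per_deg: 0.05
grid_noise_sd_db: 1.0
cutoff_asb: 10.0

# Eligibility and quality control
improvement_threshold_pct: 30.0
qc_fl_cutoff_pct: 50.0
qc_fp_cutoff_pct: 15.0
accuracy_null: 0.9

fatigue_noise_increment: 0.0
apply_qc: true
master_seed: 0
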