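# Packaged defaults for the avalanche-rescue models.
# Durations in minutes, depths/lengths in cm, angles in degrees,
# probabilities as fractions.
seed: 0
verbosity: info

survival:
  curve:
    # piecewise-linear baseline survival over burial duration
    breakpoints: [[0, 0.91], [15, 0.81], [35, 0.21], [130, 0.05]]
  mean_depth:
    intercept_cm: 80.0
    slope_cm_per_min: 0.5
  correction:
    # survival decrease per metre of extra depth, by burial-duration bin
    bins: [[20, 0.25], [40, 0.13], [60, 0.05], [120, 0.03]]

excavation:
  ramp_angle_deg: 26.0
  nominal_segment_cm: 80.0
  stretch_segment_cm: 90.0
  rate_hard_cm_per_min: 13.20
  rate_soft_cm_per_min: 25.32

generator:
  depth_log_median_cm: 100.0
  depth_log_sigma: 0.60
  depth_min_cm: 10.0
  depth_max_cm: 600.0
  duration_weight: 0.764
  duration_log_mu_short: 2.894
  duration_log_sigma_short: 0.674
  duration_log_mu_long: 4.127
  duration_log_sigma_long: 0.02
  duration_min_min: 1.0
  duration_max_min: 96.0
  air_pocket_intercept: 0.10
  air_pocket_slope_per_cm: -0.0277
  p_hard: 0.5

scenarios:
  companion_5: {search1_min: 5, treatment_min: 10, search2_min: 5}
  companion_10: {search1_min: 10, treatment_min: 10, search2_min: 5}
  organized_25: {search1_min: 25, treatment_min: 10, search2_min: 5}
  organized_40: {search1_min: 40, treatment_min: 10, search2_min: 10}
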