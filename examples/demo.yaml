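# Small synthetic demo: 6 + 6 subjects, coarse registration.
#   ccmorph run --config examples/demo.yaml
mode: synthetic
out_dir: demo_out
seed: 7
anterior_direction: "-col"
rect_mode: axis_aligned
stats_space: stereotaxic
n_template_iterations: 3
field_sigma_schedule_px: [8.0, 4.0, 2.0]
registration:
  levels: [4, 2, 1]
  iters_per_level: [80, 60, 40]
cohort:
  base_mm: 100.0
  spacing_mm: 1.0
  age_range: [19.0, 63.0]
  groups:
    CB:
      n: 6
      n_male: 3
      region_means_mm2: [330.0, 95.0, 107.26, 79.4, 225.64]
      region_sds_mm2: [45.0, 15.0, 21.67, 16.66, 31.7]
      angle_mean_deg: 109.6
      angle_sd_deg: 4.9
    NC:
      n: 6
      n_male: 3
      region_means_mm2: [330.0, 95.0, 89.64, 64.16, 260.84]
      region_sds_mm2: [45.0, 15.0, 16.51, 10.31, 41.7]
      angle_mean_deg: 113.4
      angle_sd_deg: 5.7
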