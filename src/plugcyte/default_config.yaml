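# Default pipeline configuration: three carcinoma lines with the published
# per-line diameter and beta-actin copy-number moments, scaled to a desk-size
# run (n_cells per line is configurable; the published runs used 14k-37k).
geometry:
  side_um: 8.0
  window_um: 2.5

acquisition:
  sampling_rate_khz: 100.0
  baseline_mv: 10.0
  noise_sd_mv: 1.7        # ~2% of a typical 85 mV plateau
  saturation_mv: null

calibration:
  gain_k_mv_per_um: 85.0  # puts a 1 uM cell at an 85 mV plateau
  offset_b_mv: 0.0
  concentrations_um: [0.0, 0.5, 1.0, 1.5, 2.0]
  noise_sd_mv: 0.5

populations:
  - label: A549
    n_cells: 300
    diameter_mean_um: 14.3
    diameter_sd_um: 1.9
    copies_mean: 9.9e5
    copies_sd: 4.6e5
  - label: HepG2
    n_cells: 300
    diameter_mean_um: 13.1
    diameter_sd_um: 2.2
    copies_mean: 6.8e5
    copies_sd: 4.0e5
  - label: HeLa
    n_cells: 300
    diameter_mean_um: 12.8
    diameter_sd_um: 1.6
    copies_mean: 11.4e5
    copies_sd: 5.5e5

processing:
  k_enter: 5.0
  k_exit: 2.0
  min_duration_ms: 0.5
  max_residual_frac: 0.10
  min_stable_ms: 0.05
  max_width_ms: 60.0
  doublet_tolerance: 0.25

classify:
  feature: n_p
  hidden_units: 10
  test_fraction: 0.3
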