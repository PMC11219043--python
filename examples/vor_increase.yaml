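# VOR-increase learning session: a learning group (+30% over three 10 min
# training blocks) and a non-learning group, 5 animals each.
seed: 1
design:
  protocol: vor_increase
  frequency_hz: 1.0
  peak_velocity_degps: 10.0
cohort:
  groups:
    WT:
      n_animals: 5
      gain_trajectory: [0.8, 0.88, 0.96, 1.04]
    KO:
      n_animals: 5
      gain_trajectory: [0.8, 0.8, 0.8, 0.8]
  saccade_rate_per_s: 1.0
  noise_sd_degps: 2.0
  jitter_sd: 0.05
  rate: 1000.0
analysis:
  filter: {cutoff_hz: 15.0, order: 4, zero_phase: true}
  savgol: {window_ms: 30.0, polyorder: 2}
  fit:
    threshold_degps: 31.0
    pad_ms: 50.0
    min_segment_ms: 10.0
    max_excluded_fraction: 0.45
stats:
  alpha: 0.05
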