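synthetic:
  n_subjects: 12
  sfreq: 250.0
  channels: [C1, Cz, C2, CP1, CPz, CP2, P1, Pz, P2, POz, O1, Oz, O2]
  epoch_window: [-2.9, 1.8]
  cue_onset_range: [-1.4, -1.0]
analysis:
  bands: [low, high]
  low_freqs: [4, 6, 8, 10, 12, 14, 16, 18, 20, 22, 24, 26, 28]
  high_freqs: [40, 44, 48, 52, 56, 60, 64, 68, 72, 76, 80, 84, 88, 92, 96, 100]
  factors:
    - {factor: EXP, lock: cue, window: [0.0, 1.6]}
    - {factor: PE, lock: stimulus, window: [0.0, 1.2]}
  n_perm: 500
  baseline_cue: [-0.65, -0.15]
  baseline_stimulus: [-2.6, -2.1]
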