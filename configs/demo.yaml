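# Reduced-scale demonstration: 12 simulated participants, 8 objects,
# epochs generated directly on the 200 Hz analysis axis.
design:
  n_objects: 8
  runs_per_modality:
    auditory: 2
    visual: 2
  reps_per_stim_per_run: 3
  epoch_window:
  - -100
  - 500
  fs_raw: 200
  fs_target: 200
  n_channels: 16
signal:
  snr: 3.0
  object_onset_ms: 75
  category_onset_ms: 305
  sustain_level: 0.3
  decay_ms: 150
  object_strength: 1.4
  category_strength: 0.7
n_participants: 12
schemes:
- object
- category
n_repetitions: 5
n_permutations: 2000
n_bootstrap: 1000
simulate_at_analysis_rate: true
seed: 7
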