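# One simulated play session run end to end:
# synthesize a scripted action sequence, low-pass filter it, recognize the
# actions with self-fitted templates, and score every jumping jack.
seed: 7
stages: [simulate, preprocess, segment, metrics]
script:
  - idle
  - jumping jack
  - jump forward
  - jumping jack
  - walk
  - jumping jack
profile:
  height: 1.58
  jj_frequency: 0.5
  arm_amplitude: 150
  max_ankle_spread: 0.55
  rl_amplitude_ratio: 0.9
  rl_lag: 0.04
  noise_sd: 0.003
  timing_jitter: 0.03
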