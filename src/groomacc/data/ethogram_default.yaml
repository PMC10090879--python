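behaviours:
  foraging:
    dynamic_sd_g: 0.09481
    mean_bout_s: 35.63622754491018
    posture_jitter_deg: 15.0
    posture_mean:
    - -0.573576436351046
    - 0.0
    - 0.8191520442889918
  giving_grooming:
    dynamic_sd_g: 0.0171
    mean_bout_s: 129.57647058823528
    oscillation:
      amplitude_g: 0.0208
      axis: X
      freq_hz: 2.0
      harmonic_ratio: 1.0
    posture_jitter_deg: 8.0
    posture_mean:
    - 0.0
    - 0.0
    - 1.0
  receiving_grooming:
    dynamic_sd_g: 0.01707
    mean_bout_s: 128.45454545454547
    posture_jitter_deg: 35.0
    posture_mean:
    - 0.0
    - 0.0
    - 1.0
  resting:
    dynamic_sd_g: 0.01959
    mean_bout_s: 41.59530791788856
    posture_jitter_deg: 20.0
    posture_mean:
    - 0.0
    - 0.0
    - 1.0
  running:
    dynamic_sd_g: 0.49539
    mean_bout_s: 4.112903225806452
    oscillation:
      amplitude_g: 0.5
      axis: Z
      freq_hz: 3.0
      harmonic_ratio: 0.0
    posture_jitter_deg: 8.0
    posture_mean:
    - 0.25881904510252074
    - 0.0
    - 0.9659258262890683
  walking:
    dynamic_sd_g: 0.20546
    mean_bout_s: 7.961154273029967
    oscillation:
      amplitude_g: 0.2
      axis: Z
      freq_hz: 2.0
      harmonic_ratio: 0.0
    posture_jitter_deg: 8.0
    posture_mean:
    - 0.25881904510252074
    - 0.0
    - 0.9659258262890683
transition_weights:
  foraging: 668
  giving_grooming: 170
  receiving_grooming: 121
  resting: 341
  running: 124
  walking: 901
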