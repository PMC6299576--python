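# Demo cohort: 10 phantoms with lesion burdens in [0, 0.15] and surrogate
# spirometry FEV1/FVC = 100 - 300 f + N(0, 5), clamped to (0, 130].
kind: cohort
cohort:
  n: 10
  burden_range: [0.0, 0.15]
  intercept: 100.0
  slope: 300.0
  noise_sd: 5.0
  seed: 42
phantom:
  shape: [64, 64, 64]
  spacing: [3.5, 3.5, 3.5]
  lesion_lower_bias: 0.7
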