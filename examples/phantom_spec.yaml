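# Demo phantom: one synthetic chest volume with 8% lesion burden,
# caudally predominant, reproducible from the seed.
kind: phantom
phantom:
  shape: [96, 96, 96]
  spacing: [2.5, 2.5, 2.5]
  lesion_fraction: 0.08
  lesion_lower_bias: 0.7
  seed: 17
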