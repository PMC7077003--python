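# unit-scale synthetic predictor
synthetic:
  raw_min: 0
  raw_max: 1
  reversed: false
  default_threshold: 0.5
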