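# Method registry: score conventions of commonly benchmarked predictors.
# raw_min/raw_max are each method's theoretical score bounds, used for unit
# rescaling; `reversed: true` means a LOWER raw score implies MORE effect;
# default_threshold is the method's published binary cutoff in raw units.
# Edit or extend freely — this is data, not logic.

snap2:
  raw_min: -100
  raw_max: 100
  reversed: false
  default_threshold: 0

sift:
  raw_min: 0
  raw_max: 1
  reversed: true          # SIFT: low score = damaging
  default_threshold: 0.05

polyphen2:
  raw_min: 0
  raw_max: 1
  reversed: false
  default_threshold: 0.5

envision:
  raw_min: 0
  raw_max: 2              # ~1 = wild-type-like, <1 loss, >1 gain
  reversed: true          # deleterious side: lower = more effect
  default_threshold: 0.9
  beneficial_range: [0.0, 0.2]

naive_conservation:
  raw_min: -17            # flipped PSSM log-odds scale
  raw_max: 17
  reversed: false
  default_threshold: 0
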