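# End-to-end base-case run: Birmingham Hip resurfacing (within-benchmark
# pool) versus the CeMoP total hip replacement category in men.
registry:
  synthetic: default          # or a path to a cohort-spec YAML, or csv: <path>

filters:
  allowed_asa: [1, 2]
  excluded_manufacturers: [DePuy]

survival:
  family: royston_parmar
  df: 3

comparison:
  strategy_a:
    name: rs_birmingham
    select: {device_class: RS, manufacturer: BirminghamHip}
  strategy_b:
    name: thr_cemop
    select: {thr_category: CeMoP}

benchmark:
  enabled: true
  threshold: 0.05
  age_band_width: 5
  min_events: 5
  family: weibull

ages: [40, 50, 60]
sex: male
horizons: [10, lifetime]

psa:
  n: 1000
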