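# Default synthetic cohort recipe: a mixed resurfacing/THR registry with
# staggered accrual over a 9.75-year window.  Covariate mixes follow the
# qualitative shape of a national registry (six resurfacing manufacturers,
# ASA 1-2 dominating, even head sizes 38-58 mm, ages 35-70, men larger
# heads than women).  Hazard parameters are the generator's ground truth.
n_patients: 20000
registry_window: 9.75
seed: 20140401

sex_probs: {male: 0.74, female: 0.26}
asa_probs: {1: 0.40, 2: 0.57, 3: 0.03}
device_class_probs: {RS: 0.5, THR: 0.5}

manufacturer_probs:
  BirminghamHip: 0.54
  Biomet: 0.08
  Centerpulse: 0.07
  Corin: 0.09
  Finsbury: 0.08
  WrightUK: 0.14

thr_category_probs: {CeMoP: 0.60, CeCoP: 0.25, CeLCoC: 0.15}

head_size_probs:
  male:   {38: 0.01, 40: 0.01, 42: 0.03, 44: 0.05, 46: 0.10, 48: 0.15,
           50: 0.25, 52: 0.20, 54: 0.12, 56: 0.06, 58: 0.02}
  female: {38: 0.08, 40: 0.12, 42: 0.22, 44: 0.25, 46: 0.18, 48: 0.10,
           50: 0.04, 52: 0.01}

age_band_probs:
  "35-40": 0.05
  "40-45": 0.12
  "45-50": 0.20
  "50-55": 0.26
  "55-60": 0.22
  "60-65": 0.11
  "65-70": 0.04

hazards:
  RS:
    family: bathtub
    params: {shape_early: 0.6, scale_early: 1200.0, shape_late: 2.2, scale_late: 55.0}
    log_hr:
      female: 0.7
      head_size_minus_50: -0.18
      age_minus_55: 0.03
      "manufacturer:BirminghamHip": -0.25
      "manufacturer:WrightUK": 0.25
      "manufacturer:Corin": 0.25
  THR:
    family: weibull
    params: {shape: 1.1, scale: 180.0}

loss_to_followup_rate: 0.0
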