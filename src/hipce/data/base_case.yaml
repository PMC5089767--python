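# Base-case model inputs (2014 GBP).  Each uncertain entry carries its
# published mean/SE; beta entries additionally carry the published
# alpha/beta pair.  Where a published pair is inconsistent with its own
# mean (see config.py), the moment-matched pair is used for sampling.
discount_rate: 0.035
wtp: 20000

transition:
  surgical_mortality: {mean: 0.0050, se: 0.001}
  rerevision_prob: {mean: 0.0518}          # no SE published; fixed in PSA

utilities:
  male:
    bands:
      "40-50": {mean: 0.736, se: 0.0179, alpha: 443, beta: 159}
      "50-60": {mean: 0.767, se: 0.0066, alpha: 3133, beta: 952}
      # published alpha/beta imply mean 0.792, not 0.762; moments win
      "60-70": {mean: 0.762, se: 0.0038, alpha: 9112, beta: 2393}
    revision: {mean: 0.575, se: 0.009, alpha: 1496, beta: 1106}
  female:
    bands:
      "40-50": {mean: 0.720, se: 0.0129, alpha: 872, beta: 339}
      "50-60": {mean: 0.742, se: 0.0058, alpha: 4287, beta: 1491}
      "60-70": {mean: 0.769, se: 0.0032, alpha: 13128, beta: 3944}
    revision: {mean: 0.553, se: 0.007, alpha: 2201, beta: 1779}

strategies:
  rs_birmingham:
    label: BHIP
    device_class: RS
    prosthesis: {mean: 2808}
    surgery: {mean: 1738}
    inpatient: {mean: 1628}
    followup_primary: {mean: 509, se: 44}
  thr_cemop:
    label: CeMoP
    device_class: THR
    prosthesis: {mean: 1575}
    surgery: {mean: 1738}
    inpatient: {mean: 1687}
    followup_primary: {mean: 400, se: 30}
  thr_cecop:
    label: CeCoP
    device_class: THR
    prosthesis: {mean: 2018}
    surgery: {mean: 1738}
    inpatient: {mean: 1687}
    followup_primary: {mean: 400, se: 30}
  thr_celcoc:
    label: CeLCoC
    device_class: THR
    prosthesis: {mean: 3911}
    surgery: {mean: 1738}
    inpatient: {mean: 1687}
    followup_primary: {mean: 400, se: 30}

shared_costs:
  revision_surgery: {mean: 16794, se: 443}
  followup_postrevision: {mean: 400, se: 30}

# Pre-inflation figures quoted in the source text; not used by default.
alternative_costs:
  revision_surgery: {mean: 16517}
  followup_postrevision: {mean: 394}

# Scenario slots.  The supplements carrying their numeric contents are not
# reproduced here; values remain placeholders until supplied by the user.
scenarios:
  edlin_utility:
    qaly_increment_rs: null        # placeholder (S2-style utility advantage)
    duration_cycles: 2             # applied for the first two years
  manufacturer_costs: null         # placeholder (S4-style device costs)

life_table:
  male: {makeham_a: 0.0004, gompertz_b: 3.0e-5, gompertz_c: 0.098}
  female: {makeham_a: 0.0002, gompertz_b: 1.6e-5, gompertz_c: 0.102}
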