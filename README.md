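# hipce

Registry-based lifetime cost-utility analysis of hip implant strategies:
metal-on-metal resurfacing (RS) versus total hip replacement (THR).

The package covers the full analysis chain:

1. **`hipce.registry`** — synthetic registry cohorts with known ground
   truth (staggered accrual, administrative censoring, parametric revision
   hazards with covariate effects), registry filtering rules, and
   Gompertz–Makeham life tables.
2. **`hipce.survival`** — Kaplan–Meier with Greenwood variance, a flexible
   parametric model (restricted cubic spline on the log cumulative hazard
   against log time; one degree of freedom is exactly Weibull), and
   maximum-likelihood fits for Weibull, Gompertz, log-logistic,
   generalised-gamma and an additive two-Weibull "bathtub" hazard, all with
   proportional covariate effects.  Fits convert to annual conditional
   revision probabilities.
3. **`hipce.benchmark`** — classification of (manufacturer, sex, head size,
   age band) subgroups against the <5%-at-10-years revision benchmark, and
   dichotomisation of a registry into within / not-within pools.
4. **`hipce.markov`** — four-state annual-cycle cohort model (successful
   primary, revision surgery for exactly one cycle, successful revision,
   dead) with 3.5% discounting, 10-year and lifetime (to age 100) horizons,
   and incremental comparisons (ICER, dominance, net monetary benefit).
5. **`hipce.psa`** — probabilistic sensitivity analysis with Beta/Gamma
   input distributions, shared draws for parameters common to both arms,
   and cost-effectiveness acceptability curves.
6. **`hipce.pipeline` / `hipce.cli`** — configuration-driven end-to-end
   runs with artifact output and a formatted results table.

The shipped `src/hipce/data/base_case.yaml` encodes the published
base-case inputs (costs in 2014 GBP, utilities with Beta parameters,
transition inputs); `synthetic_cohort.yaml` is the default cohort recipe;
`run_base_case.yaml` wires the base-case comparison (Birmingham Hip
within-benchmark pool versus the CeMoP THR category in men).

## CLI

```sh
hipce simulate --seed 1 --out registry.csv            # synthetic cohort
hipce fit --registry registry.csv --family royston_parmar --df 3 --out fit.json
hipce benchmark --registry registry.csv --out decisions.csv
hipce run --seed 1 --out run_dir                      # full pipeline
hipce psa --n 1000 --seed 1 --out run_dir             # pipeline with PSA size
```

All commands accept `--config PATH` to override the shipped YAML defaults;
`hipce run`/`hipce psa` also accept `--inputs PATH` for the model-input
bundle.

## Python API sketch

```python
from hipce import config, registry, survival, markov, psa

spec = config.load_cohort_spec()
cohort = registry.generate_registry(spec, seed=1)
fit = survival.fit_royston_parmar(cohort, df=3, covariates=("age_at_primary",))
sched = survival.annual_transition_probs(fit, {"age_at_primary": 50}, horizon=60)

cfg = config.load_base_case()
inputs = config.build_model_inputs(cfg, "rs_birmingham", sched)
result = markov.run_cohort(inputs, start_age=50, sex="male", horizon="lifetime")
```

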