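"""Loading of model-input and cohort configuration files.

The shipped ``data/base_case.yaml`` encodes the published base-case inputs:
transition probabilities, state utilities with Beta uncertainty, and cost
sets with Gamma uncertainty.  This module turns that file into the typed
objects the cohort model and PSA consume.

Sampling-distribution policy: a published Beta pair is used verbatim when
its implied mean agrees with the published mean to 3 decimal places;
otherwise (one utility row is internally inconsistent) the method-of-moments
pair wins.  Published Gamma pairs are rounded too coarsely to reproduce
their means under any convention, so cost Gammas are always moment-matched.
"""

from __future__ import annotations

import importlib.resources
import logging
from pathlib import Path
from typing import Dict, Optional, Tuple

import yaml

from .markov import ModelInputs, StrategyCosts, Utilities
from .psa import DistributionSpec, beta_mean
from .registry import CohortSpec, HazardSpec, LifeTable, make_life_table
from .survival import AnnualRevisionSchedule

__all__ = [
    "load_yaml",
    "load_base_case",
    "load_run_config",
    "load_cohort_spec",
    "utility_distribution",
    "cost_distribution",
    "build_utilities",
    "build_life_table",
    "build_strategy_costs",
    "build_model_inputs",
    "table1_distributions",
    "make_psa_builder",
]

log = logging.getLogger(__name__)

_DATA = importlib.resources.files("hipce") / "data"


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def load_base_case(path: Optional[str] = None) -> dict:
    """The shipped base-case model inputs (or a user-supplied override)."""
    if path is not None:
        return load_yaml(path)
    return yaml.safe_load((_DATA / "base_case.yaml").read_text())


def load_run_config(path: Optional[str] = None) -> dict:
    if path is not None:
        return load_yaml(path)
    return yaml.safe_load((_DATA / "run_base_case.yaml").read_text())


def _parse_band(key: str) -> Tuple[int, int]:
    lo, hi = key.split("-")
    return int(lo), int(hi)


def load_cohort_spec(path: Optional[str] = None) -> CohortSpec:
    """Parse a cohort-spec YAML into a validated CohortSpec."""
    if path is None:
        raw = yaml.safe_load((_DATA / "synthetic_cohort.yaml").read_text())
    else:
        raw = load_yaml(path)
    hazards = {
        cls: HazardSpec(
            family=h["family"],
            params={k: float(v) for k, v in h["params"].items()},
            log_hr={k: float(v) for k, v in h.get("log_hr", {}).items()},
        )
        for cls, h in raw.get("hazards", {}).items()
    }
    death = raw.get("death_hazard")
    spec = CohortSpec(
        n_patients=int(raw["n_patients"]),
        registry_window=float(raw.get("registry_window", 9.75)),
        seed=raw.get("seed"),
        sex_probs={k: float(v) for k, v in raw["sex_probs"].items()},
        asa_probs={int(k): float(v) for k, v in raw["asa_probs"].items()},
        device_class_probs={k: float(v) for k, v in raw["device_class_probs"].items()},
        manufacturer_probs={k: float(v) for k, v in raw["manufacturer_probs"].items()},
        thr_category_probs={k: float(v) for k, v in raw["thr_category_probs"].items()},
        head_size_probs={
            sex: {int(k): float(v) for k, v in probs.items()}
            for sex, probs in raw["head_size_probs"].items()
        },
        age_band_probs={
            _parse_band(k): float(v) for k, v in raw["age_band_probs"].items()
        },
        hazards=hazards,
        loss_to_followup_rate=float(raw.get("loss_to_followup_rate", 0.0)),
        death_hazard=None
        if death is None
        else HazardSpec(
            family=death["family"],
            params={k: float(v) for k, v in death["params"].items()},
        ),
    )
    spec.validate()
    return spec


def utility_distribution(row: dict) -> DistributionSpec:
    """Beta spec for one utility row, preferring the published pair when it
    is consistent with the published mean (3 d.p.)."""
    mean, se = float(row["mean"]), float(row["se"])
    alpha, beta = row.get("alpha"), row.get("beta")
    if alpha is not None and beta is not None:
        if round(beta_mean(float(alpha), float(beta)), 3) == round(mean, 3):
            return DistributionSpec.beta(
                float(alpha), float(beta), source_mean=mean, source_se=se
            )
        log.info(
            "published Beta pair (%s, %s) inconsistent with mean %.3f; "
            "using moment-matched parameters",
            alpha, beta, mean,
        )
    return DistributionSpec.beta_moments(mean, se)


def cost_distribution(row: dict) -> DistributionSpec:
    """Gamma spec for a cost row; fixed when no SE is published."""
    mean = float(row["mean"])
    if row.get("se") is None:
        return DistributionSpec.fixed(mean, source_mean=mean)
    return DistributionSpec.gamma_moments(mean, float(row["se"]))


def build_utilities(cfg: dict, draws: Optional[Dict[str, float]] = None) -> Utilities:
    draws = draws or {}
    successful: Dict[Tuple[str, int], float] = {}
    revision: Dict[str, float] = {}
    for sex, block in cfg["utilities"].items():
        for band_key, row in block["bands"].items():
            lo, _ = _parse_band(band_key)
            name = f"utility:{sex}:{band_key}"
            successful[(sex, lo)] = draws.get(name, float(row["mean"]))
        name = f"utility:{sex}:revision"
        revision[sex] = draws.get(name, float(block["revision"]["mean"]))
    return Utilities(successful=successful, revision=revision)


def build_life_table(cfg: dict) -> LifeTable:
    tables = []
    for sex, p in cfg["life_table"].items():
        tables.append(
            make_life_table(
                sex,
                makeham_a=float(p["makeham_a"]),
                gompertz_b=float(p["gompertz_b"]),
                gompertz_c=float(p["gompertz_c"]),
            )
        )
    return LifeTable.concat(tables)


def build_strategy_costs(
    cfg: dict, strategy: str, draws: Optional[Dict[str, float]] = None
) -> StrategyCosts:
    draws = draws or {}
    s = cfg["strategies"][strategy]
    shared = cfg["shared_costs"]
    return StrategyCosts(
        prosthesis=draws.get(f"cost:prosthesis:{strategy}", float(s["prosthesis"]["mean"])),
        surgery=draws.get(f"cost:surgery:{strategy}", float(s["surgery"]["mean"])),
        inpatient=draws.get(f"cost:inpatient:{strategy}", float(s["inpatient"]["mean"])),
        followup_primary=draws.get(
            f"cost:followup_primary:{strategy}", float(s["followup_primary"]["mean"])
        ),
        revision_surgery=draws.get(
            "cost:revision_surgery", float(shared["revision_surgery"]["mean"])
        ),
        followup_postrevision=draws.get(
            "cost:followup_postrevision", float(shared["followup_postrevision"]["mean"])
        ),
    )


def build_model_inputs(
    cfg: dict,
    strategy: str,
    schedule: AnnualRevisionSchedule,
    life_table: Optional[LifeTable] = None,
    draws: Optional[Dict[str, float]] = None,
) -> ModelInputs:
    """Assemble one strategy arm from config means, optionally overridden by
    a PSA draw dict keyed by parameter name."""
    draws = draws or {}
    return ModelInputs(
        surgical_mortality=draws.get(
            "surgical_mortality", float(cfg["transition"]["surgical_mortality"]["mean"])
        ),
        rerevision_prob=draws.get(
            "rerevision_prob", float(cfg["transition"]["rerevision_prob"]["mean"])
        ),
        revision_schedule=schedule,
        life_table=life_table if life_table is not None else build_life_table(cfg),
        utilities=build_utilities(cfg, draws),
        costs=build_strategy_costs(cfg, strategy, draws),
        discount_rate=float(cfg.get("discount_rate", 0.035)),
        wtp=float(cfg.get("wtp", 20_000.0)),
    )


def table1_distributions(
    cfg: dict, strategies: Tuple[str, ...] = ()
) -> Dict[str, DistributionSpec]:
    """Named uncertainty distributions for the PSA.

    Shared parameters (utilities, surgical mortality, revision-surgery and
    post-revision follow-up costs) carry one name each, so one draw per
    iteration feeds both arms; per-strategy follow-up costs are keyed by
    strategy.  The re-revision probability has no published SE and stays
    fixed.
    """
    dists: Dict[str, DistributionSpec] = {}
    tr = cfg["transition"]["surgical_mortality"]
    dists["surgical_mortality"] = DistributionSpec.beta_moments(
        float(tr["mean"]), float(tr["se"])
    )
    for sex, block in cfg["utilities"].items():
        for band_key, row in block["bands"].items():
            dists[f"utility:{sex}:{band_key}"] = utility_distribution(row)
        dists[f"utility:{sex}:revision"] = utility_distribution(block["revision"])
    dists["cost:revision_surgery"] = cost_distribution(
        cfg["shared_costs"]["revision_surgery"]
    )
    dists["cost:followup_postrevision"] = cost_distribution(
        cfg["shared_costs"]["followup_postrevision"]
    )
    for strategy in strategies:
        row = cfg["strategies"][strategy]["followup_primary"]
        dists[f"cost:followup_primary:{strategy}"] = cost_distribution(row)
    return dists


def make_psa_builder(
    cfg: dict,
    strategy_a: str,
    strategy_b: str,
    schedule_a: AnnualRevisionSchedule,
    schedule_b: AnnualRevisionSchedule,
    life_table: Optional[LifeTable] = None,
):
    """(distributions, build_inputs) pair ready for :func:`hipce.psa.run_psa`."""
    lt = life_table if life_table is not None else build_life_table(cfg)
    dists = table1_distributions(cfg, strategies=(strategy_a, strategy_b))

    def build_inputs(draws: Dict[str, float]):
        a = build_model_inputs(cfg, strategy_a, schedule_a, lt, draws)
        b = build_model_inputs(cfg, strategy_b, schedule_b, lt, draws)
        return a, b

    return dists, build_inputs
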