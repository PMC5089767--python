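"""End-to-end orchestration: registry -> filter -> survival fit ->
benchmark pooling -> cohort model -> PSA -> results table and artifacts."""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .benchmark import classify_cohort, decisions_to_frame, dichotomize
from .config import (
    build_life_table,
    build_model_inputs,
    load_base_case,
    load_cohort_spec,
    make_psa_builder,
)
from .markov import compare_strategies, run_cohort
from .psa import run_psa
from .registry import (
    FilterRules,
    filter_registry,
    generate_registry,
    read_registry_csv,
    write_registry_csv,
)
from .survival import annual_transition_probs, fit_parametric, fit_royston_parmar

__all__ = ["run_pipeline", "render_table2", "PipelineError"]

log = logging.getLogger(__name__)

AGE_COVARIATE = "age_at_primary"


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def _load_registry(reg_cfg: dict, seed: Optional[int]):
    if "csv" in reg_cfg:
        return read_registry_csv(reg_cfg["csv"])
    synthetic = reg_cfg.get("synthetic", "default")
    spec = load_cohort_spec(None if synthetic == "default" else synthetic)
    if seed is not None:
        spec.seed = seed
    log.info("generating synthetic registry: n=%d seed=%s", spec.n_patients, spec.seed)
    return generate_registry(spec)


def _select(registry: pd.DataFrame, select: Dict[str, object]) -> pd.DataFrame:
    mask = pd.Series(True, index=registry.index)
    for col, val in select.items():
        mask &= registry[col] == val
    return registry.loc[mask]


def _fit(records: pd.DataFrame, surv_cfg: dict):
    family = surv_cfg.get("family", "royston_parmar")
    if family == "royston_parmar":
        return fit_royston_parmar(
            records, df=int(surv_cfg.get("df", 3)), covariates=(AGE_COVARIATE,)
        )
    return fit_parametric(records, family, covariates=(AGE_COVARIATE,))


def run_pipeline(
    run_cfg: dict,
    model_cfg: Optional[dict] = None,
    seed: Optional[int] = None,
    out_dir=None,
) -> pd.DataFrame:
    """Execute the full analysis; returns the results table.

    When ``out_dir`` is given, artifacts (registry sample, fit summaries,
    benchmark decisions, CEAC curves, the results table and a manifest) are
    written there.
    """
    cfg = model_cfg if model_cfg is not None else load_base_case()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    registry = _stage("registry")(_load_registry)(run_cfg["registry"], seed)

    rules_cfg = run_cfg.get("filters", {})
    rules = FilterRules(
        allowed_asa=rules_cfg.get("allowed_asa"),
        excluded_manufacturers=rules_cfg.get("excluded_manufacturers"),
        allowed_device_classes=rules_cfg.get("allowed_device_classes"),
    )
    fres = _stage("filter")(filter_registry)(registry, rules)
    log.info("filter removed %s", fres.removed)
    registry = fres.records
    sex = run_cfg.get("sex", "male")
    registry_sex = registry[registry["sex"] == sex]

    comp = run_cfg["comparison"]
    name_a, name_b = comp["strategy_a"]["name"], comp["strategy_b"]["name"]
    records_a = _select(registry_sex, comp["strategy_a"]["select"])
    records_b = _select(registry_sex, comp["strategy_b"]["select"])

    bench_cfg = run_cfg.get("benchmark", {})
    decisions = None
    if bench_cfg.get("enabled", False):
        width = int(bench_cfg.get("age_band_width", 5))
        decisions = _stage("benchmark")(classify_cohort)(
            records_a,
            threshold=float(bench_cfg.get("threshold", 0.05)),
            age_bands=[(a, a + width) for a in range(30, 90, width)],
            family=bench_cfg.get("family", "weibull"),
            min_events=int(bench_cfg.get("min_events", 5)),
        )
        pools = dichotomize(records_a, decisions)
        log.info(
            "benchmark: %.1f%% of strategy-A records within threshold",
            100.0 * pools.proportion_within,
        )
        if len(pools.within) and int(pools.within["revised"].sum()) >= 10:
            records_a = pools.within
        else:
            warnings.warn(
                "within-benchmark pool too small to refit; using all records"
            )

    surv_cfg = run_cfg.get("survival", {})
    fit_a = _stage("fit")(_fit)(records_a, surv_cfg)
    fit_b = _stage("fit")(_fit)(records_b, surv_cfg)

    life_table = build_life_table(cfg)
    psa_cfg = run_cfg.get("psa", {})
    n_psa = int(psa_cfg.get("n", 1000))
    ages = [int(a) for a in run_cfg.get("ages", [40, 50, 60])]
    horizons = run_cfg.get("horizons", [10, "lifetime"])

    rows = []
    ceac_frames = []
    for age in ages:
        for horizon in horizons:
            cycles = (
                100 - age if horizon == "lifetime" else int(str(horizon).rstrip("y"))
            )
            cov = {AGE_COVARIATE: float(age)}
            sched_a = annual_transition_probs(fit_a, cov, horizon=max(cycles, 1))
            sched_b = annual_transition_probs(fit_b, cov, horizon=max(cycles, 1))
            inputs_a = build_model_inputs(cfg, name_a, sched_a, life_table)
            inputs_b = build_model_inputs(cfg, name_b, sched_b, life_table)
            res_a = run_cohort(inputs_a, age, sex, horizon, strategy=name_a)
            res_b = run_cohort(inputs_b, age, sex, horizon, strategy=name_b)
            comparison = compare_strategies(res_a, res_b, wtp=inputs_a.wtp)

            p_ce = np.nan
            if n_psa > 0:
                dists, builder = make_psa_builder(
                    cfg, name_a, name_b, sched_a, sched_b, life_table
                )
                psa_res = _stage("psa")(run_psa)(
                    dists, builder, age, sex, horizon, n=n_psa, seed=seed
                )
                p_ce = psa_res.prob_cost_effective(inputs_a.wtp)
                curve = psa_res.ceac()
                curve.insert(0, "age", age)
                curve.insert(1, "horizon", res_a.horizon)
                ceac_frames.append(curve)
                if out is not None:
                    psa_res.to_csv(out / f"psa_{sex}_{age}_{res_a.horizon}.csv")

            rows.append(
                {
                    "sex": sex,
                    "age": age,
                    "horizon": res_a.horizon,
                    "strategy_a": name_a,
                    "strategy_b": name_b,
                    "cost_a": res_a.total_cost,
                    "qalys_a": res_a.total_qalys,
                    "cost_b": res_b.total_cost,
                    "qalys_b": res_b.total_qalys,
                    "delta_cost": comparison.delta_cost,
                    "delta_qalys": comparison.delta_qalys,
                    "icer": comparison.icer,
                    "label": comparison.label,
                    "prob_ce_at_wtp": p_ce,
                }
            )
            if out is not None:
                res_a.trace.to_csv(
                    out / f"trace_{name_a}_{sex}_{age}_{res_a.horizon}.csv", index=False
                )
                res_b.trace.to_csv(
                    out / f"trace_{name_b}_{sex}_{age}_{res_b.horizon}.csv", index=False
                )

    results = pd.DataFrame(rows)

    if out is not None:
        write_registry_csv(registry.head(1000), out / "registry_sample.csv")
        fit_a.to_json(out / f"fit_{name_a}.json")
        fit_b.to_json(out / f"fit_{name_b}.json")
        if decisions is not None:
            decisions_to_frame(decisions).to_csv(
                out / "benchmark_decisions.csv", index=False
            )
        if ceac_frames:
            pd.concat(ceac_frames, ignore_index=True).to_csv(
                out / "ceac.csv", index=False
            )
        results.to_csv(out / "results.csv", index=False)
        manifest = {
            "config_hash": hashlib.sha256(
                yaml.safe_dump(run_cfg, sort_keys=True).encode()
            ).hexdigest(),
            "seed": seed,
            "package_version": __version__,
            "n_records_after_filter": int(len(registry)),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)

    return results


def _fmt_cost(x: float) -> str:
    return f"{x:,.0f}"


def _fmt_icer(row) -> str:
    if row["label"] == "dominated":
        return "Dominated"
    if row["label"] == "dominant":
        return "Dominant"
    if row["icer"] is None or (isinstance(row["icer"], float) and np.isnan(row["icer"])):
        return "—"
    return f"{row['icer']:,.0f}"


def render_table2(results: pd.DataFrame) -> str:
    """Format the results table: whole-pound costs with thousands
    separators, QALYs to 4 d.p., ICER as pounds or a dominance label."""
    if results.empty:
        warnings.warn("results table is empty")
        return ""
    lines = []
    for (sex, horizon), block in results.groupby(["sex", "horizon"], sort=True):
        label = "Lifetime horizon" if horizon == "lifetime" else f"{horizon} time horizon"
        lines.append(f"{sex.capitalize()}: {label}")
        header = ["", *[f"Age {a}" for a in block["age"]]]
        rows = {
            "Total mean costs £ (A)": [_fmt_cost(v) for v in block["cost_a"]],
            "Total mean costs £ (B)": [_fmt_cost(v) for v in block["cost_b"]],
            "Total mean QALYs (A)": [f"{v:.4f}" for v in block["qalys_a"]],
            "Total mean QALYs (B)": [f"{v:.4f}" for v in block["qalys_b"]],
            "Incremental cost £": [_fmt_cost(v) for v in block["delta_cost"]],
            "Incremental QALYs": [f"{v:.4f}" for v in block["delta_qalys"]],
            "ICER (£/QALY)": [_fmt_icer(r) for _, r in block.iterrows()],
            "P(cost-effective)": [
                "—" if np.isnan(v) else f"{v:.2f}" for v in block["prob_ce_at_wtp"]
            ],
        }
        widths = [max(len(h), 22) for h in header]
        lines.append("  ".join(h.ljust(w) for h, w in zip(header, widths)))
        for name, vals in rows.items():
            cells = [name, *vals]
            lines.append("  ".join(c.ljust(w) for c, w in zip(cells, widths)))
        lines.append("")
    return "\n".join(lines)
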