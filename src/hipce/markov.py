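"""Four-state annual-cycle cohort model.

States: successful primary implant, revision surgery (occupied for exactly
one cycle), successful revision, dead.  Each cycle the cohort ages one
year; background mortality comes from a life table, device failure from an
annual revision schedule, and re-revision from a constant annual risk.

Accounting conventions (all switchable only by editing, documented here and
exercised by the path-enumeration oracle in the test suite):

* cycle 0 is the primary operation: everyone pays the primary procedure
  cost (prosthesis + surgery + inpatient stay), operative mortality is
  applied, and survivors accrue the successful-state utility undiscounted;
* in later cycles, background death is applied first; survivors may then
  attempt (re-)revision — every attempt pays the revision cost and carries
  operative mortality; operative deaths accrue no utility that cycle;
* follow-up costs and utilities accrue on end-of-cycle occupancy;
* discounting starts at cycle 1; the dead state accrues nothing;
* no half-cycle correction (`half_cycle_correction` retains the hook).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .registry import LifeTable
from .survival import AnnualRevisionSchedule

__all__ = [
    "STATES",
    "UTILITY_BANDS",
    "Utilities",
    "StrategyCosts",
    "ModelInputs",
    "StrategyResult",
    "Comparison",
    "discount_factor",
    "run_cohort",
    "compare_strategies",
]

STATES = ("successful_primary", "revision_surgery", "successful_revision", "dead")
UTILITY_BANDS = ((40, 50), (50, 60), (60, 70))


def discount_factor(cycle: int, rate: float) -> float:
    """1 / (1 + rate)^cycle."""
    if cycle < 0 or int(cycle) != cycle:
        raise ValueError("cycle must be a non-negative integer")
    if rate < 0:
        raise ValueError("rate must be non-negative")
    return 1.0 / (1.0 + rate) ** int(cycle)


@dataclass
class Utilities:
    """State utilities by sex and age band.

    ``successful`` maps (sex, band_lo) to the successful-state utility;
    ``revision`` maps sex to the revision-cycle utility.  Ages below the
    lowest band use the lowest band; ages at or above the highest band's
    upper limit use the highest band.
    """

    successful: Dict[Tuple[str, int], float]
    revision: Dict[str, float]

    def successful_at(self, sex: str, age: float) -> float:
        lo = self._band_lo(age)
        try:
            return self.successful[(sex, lo)]
        except KeyError:
            raise KeyError(f"no utility for sex={sex!r}, band starting {lo}") from None

    def revision_for(self, sex: str) -> float:
        return self.revision[sex]

    @staticmethod
    def _band_lo(age: float) -> int:
        if age < UTILITY_BANDS[0][0]:
            return UTILITY_BANDS[0][0]
        for lo, hi in UTILITY_BANDS:
            if lo <= age < hi:
                return lo
        return UTILITY_BANDS[-1][0]

    @classmethod
    def constant(cls, u_success: float, u_revision: float, sexes=("male", "female")):
        return cls(
            successful={(s, lo): u_success for s in sexes for lo, _ in UTILITY_BANDS},
            revision={s: u_revision for s in sexes},
        )

    def validate(self) -> None:
        for val in list(self.successful.values()) + list(self.revision.values()):
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"utility {val} outside [0, 1]")


@dataclass
class StrategyCosts:
    """Per-strategy cost set (GBP)."""

    prosthesis: float
    surgery: float
    inpatient: float
    followup_primary: float
    revision_surgery: float
    followup_postrevision: float

    @property
    def primary_procedure(self) -> float:
        return self.prosthesis + self.surgery + self.inpatient

    def validate(self) -> None:
        for name in (
            "prosthesis",
            "surgery",
            "inpatient",
            "followup_primary",
            "revision_surgery",
            "followup_postrevision",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"cost {name!r} must be non-negative")


@dataclass
class ModelInputs:
    """Everything one strategy needs to run through the cohort model."""

    surgical_mortality: float
    rerevision_prob: float
    revision_schedule: AnnualRevisionSchedule
    life_table: LifeTable
    utilities: Utilities
    costs: StrategyCosts
    discount_rate: float = 0.035
    wtp: float = 20_000.0
    half_cycle_correction: bool = False

    def validate(self) -> None:
        for name in ("surgical_mortality", "rerevision_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.discount_rate < 0:
            raise ValueError("discount_rate must be non-negative")
        self.utilities.validate()
        self.costs.validate()


@dataclass
class StrategyResult:
    strategy: str
    horizon: str
    cycles: int
    total_cost: float
    total_qalys: float
    trace: Optional[pd.DataFrame] = None

    @classmethod
    def from_totals(
        cls, strategy: str, horizon: str, total_cost: float, total_qalys: float
    ) -> "StrategyResult":
        """Build a result from externally supplied totals (no trace)."""
        return cls(strategy, horizon, 0, float(total_cost), float(total_qalys))


def _horizon_cycles(horizon: Union[int, str], start_age: int, max_age: int = 100) -> Tuple[int, str]:
    if isinstance(horizon, str):
        if horizon == "lifetime":
            return max(max_age - start_age, 1), "lifetime"
        if horizon.endswith("y"):
            return int(horizon[:-1]), horizon
        raise ValueError(f"unrecognised horizon {horizon!r}")
    return int(horizon), f"{int(horizon)}y"


def run_cohort(
    inputs: ModelInputs,
    start_age: int,
    sex: str,
    horizon: Union[int, str] = "lifetime",
    strategy: str = "strategy",
) -> StrategyResult:
    """Run the cohort through ``horizon`` annual cycles from ``start_age``."""
    inputs.validate()
    cycles, horizon_label = _horizon_cycles(horizon, start_age)
    sched = inputs.revision_schedule.probs
    if cycles > 1 and sched.size < cycles - 1:
        raise ValueError(
            f"revision schedule covers {sched.size} cycles; horizon needs {cycles - 1}"
        )
    m = inputs.surgical_mortality
    r = inputs.rerevision_prob
    costs = inputs.costs
    rate = inputs.discount_rate

    rows = []
    # cycle 0: primary operation
    sp = 1.0 - m
    rv = 0.0
    sr = 0.0
    dead = m
    u = inputs.utilities.successful_at(sex, start_age)
    cost0 = costs.primary_procedure + sp * costs.followup_primary
    qaly0 = sp * u
    rows.append((0, start_age, sp, rv, sr, dead, cost0, qaly0, cost0, qaly0))

    for t in range(1, cycles):
        age = start_age + t
        qx = inputs.life_table.qx(sex, age)
        p = sched[t - 1]

        attempts = sp * (1 - qx) * p + sr * (1 - qx) * r
        new_rv = attempts * (1 - m)
        new_sr = rv * (1 - qx) + sr * (1 - qx) * (1 - r)
        new_sp = sp * (1 - qx) * (1 - p)
        new_dead = dead + qx * (sp + rv + sr) + attempts * m

        cost_t = (
            attempts * costs.revision_surgery
            + new_sp * costs.followup_primary
            + new_sr * costs.followup_postrevision
        )
        u_s = inputs.utilities.successful_at(sex, age)
        u_r = inputs.utilities.revision_for(sex)
        qaly_t = (new_sp + new_sr) * u_s + new_rv * u_r

        disc = discount_factor(t, rate)
        sp, rv, sr, dead = new_sp, new_rv, new_sr, new_dead
        rows.append(
            (t, age, sp, rv, sr, dead, cost_t, qaly_t, cost_t * disc, qaly_t * disc)
        )

    trace = pd.DataFrame(
        rows,
        columns=[
            "cycle",
            "age",
            "successful_primary",
            "revision_surgery",
            "successful_revision",
            "dead",
            "cost",
            "qaly",
            "disc_cost",
            "disc_qaly",
        ],
    )
    return StrategyResult(
        strategy=strategy,
        horizon=horizon_label,
        cycles=cycles,
        total_cost=float(trace["disc_cost"].sum()),
        total_qalys=float(trace["disc_qaly"].sum()),
        trace=trace,
    )


@dataclass
class Comparison:
    """Incremental result of strategy A versus strategy B."""

    strategy_a: str
    strategy_b: str
    delta_cost: float
    delta_qalys: float
    icer: Optional[float]
    label: str
    nmb: float
    wtp: float

    ICER_UNDEFINED = "ICER undefined (no QALY difference)"


def compare_strategies(
    a: StrategyResult, b: StrategyResult, wtp: float = 20_000.0
) -> Comparison:
    """Incremental cost, QALYs, ICER/dominance label and net monetary benefit."""
    if a.horizon != b.horizon:
        raise ValueError(
            f"horizon mismatch: {a.horizon!r} vs {b.horizon!r}; strategies must share one"
        )
    d_cost = a.total_cost - b.total_cost
    d_qaly = a.total_qalys - b.total_qalys
    nmb = wtp * d_qaly - d_cost
    if d_qaly == 0.0:
        icer = None
        label = "equivalent" if d_cost == 0.0 else Comparison.ICER_UNDEFINED
    elif d_cost < 0 and d_qaly > 0:
        icer = None
        label = "dominant"
    elif d_cost > 0 and d_qaly < 0:
        icer = None
        label = "dominated"
    else:
        icer = d_cost / d_qaly
        label = "icer"
    return Comparison(
        strategy_a=a.strategy,
        strategy_b=b.strategy,
        delta_cost=d_cost,
        delta_qalys=d_qaly,
        icer=icer,
        label=label,
        nmb=nmb,
        wtp=wtp,
    )
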