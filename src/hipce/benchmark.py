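"""Classification of device-patient subgroups against the 10-year revision
benchmark (<5% predicted cumulative revision at 10 years) and pooling of
registry records into within / not-within strata.

Fits are stratified by manufacturer, sex and head size, with age at primary
as a linear covariate; subgroup decisions use the point prediction at the
age-band midpoint.  Subgroup cells with fewer than ``min_events`` events
inherit the parent (manufacturer x sex) decision and are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .survival import SurvivalFit, fit_parametric, predict_cumulative_revision

__all__ = [
    "SubgroupKey",
    "BenchmarkDecision",
    "DichotomyResult",
    "classify_subgroup",
    "classify_cohort",
    "dichotomize",
    "decisions_to_frame",
    "default_age_bands",
]

AGE_COVARIATE = "age_at_primary"


@dataclass(frozen=True)
class SubgroupKey:
    manufacturer: str
    sex: str
    head_size: float
    age_lo: float
    age_hi: float

    def __post_init__(self):
        if self.age_lo >= self.age_hi:
            raise ValueError("age band must satisfy lo < hi")

    @property
    def age_mid(self) -> float:
        return 0.5 * (self.age_lo + self.age_hi)


@dataclass
class BenchmarkDecision:
    subgroup: SubgroupKey
    predicted_10y_revision: float
    threshold: float
    within: bool
    n_patients: int
    n_events: int = 0
    flagged: bool = False
    extrapolated: bool = False


def classify_subgroup(
    fit: SurvivalFit,
    subgroup: SubgroupKey,
    threshold: float = 0.05,
    horizon: float = 10.0,
    n_patients: int = 0,
    n_events: int = 0,
) -> BenchmarkDecision:
    """Compare the point prediction at ``horizon`` years with ``threshold``."""
    cov = {AGE_COVARIATE: subgroup.age_mid} if AGE_COVARIATE in fit.beta else {}
    pred = float(predict_cumulative_revision(fit, horizon, cov))
    return BenchmarkDecision(
        subgroup=subgroup,
        predicted_10y_revision=pred,
        threshold=threshold,
        within=pred < threshold,
        n_patients=n_patients,
        n_events=n_events,
        extrapolated=fit.is_extrapolated(cov),
    )


def default_age_bands(width: int = 5, lo: int = 30, hi: int = 90) -> List[Tuple[int, int]]:
    return [(a, a + width) for a in range(lo, hi, width)]


def _band_for(age: float, bands: Sequence[Tuple[float, float]]):
    for lo, hi in bands:
        if lo <= age < hi:
            return (lo, hi)
    return None


def classify_cohort(
    registry: pd.DataFrame,
    threshold: float = 0.05,
    horizon: float = 10.0,
    age_bands: Optional[Sequence[Tuple[float, float]]] = None,
    family: str = "weibull",
    min_events: int = 5,
    min_fit_events: int = 10,
) -> List[BenchmarkDecision]:
    """Produce one decision per observed (manufacturer, sex, head size,
    age band) subgroup of the device-class-RS records."""
    rs = registry[registry["device_class"] == "RS"]
    if rs.empty:
        raise ValueError("registry contains no records with device_class == 'RS'")
    bands = list(age_bands) if age_bands is not None else default_age_bands()

    # sex-level fallback fits for strata too sparse to support their own
    sex_fits = {}
    for sex, pooled in rs.groupby("sex", sort=True):
        if int(pooled["revised"].sum()) >= min_fit_events:
            sex_fits[sex] = fit_parametric(pooled, family, covariates=(AGE_COVARIATE,))

    decisions: List[BenchmarkDecision] = []
    for (man, sex), parent in rs.groupby(["manufacturer", "sex"], sort=True):
        parent_fit = None
        if int(parent["revised"].sum()) >= min_fit_events:
            parent_fit = fit_parametric(parent, family, covariates=(AGE_COVARIATE,))
        if parent_fit is None or not parent_fit.converged:
            parent_fit = sex_fits.get(sex)
        for hs, stratum in parent.groupby("head_size", sort=True):
            stratum_fit = None
            if int(stratum["revised"].sum()) >= min_fit_events:
                stratum_fit = fit_parametric(
                    stratum, family, covariates=(AGE_COVARIATE,)
                )
            for (lo, hi) in bands:
                cell = stratum[
                    (stratum[AGE_COVARIATE] >= lo) & (stratum[AGE_COVARIATE] < hi)
                ]
                if cell.empty:
                    continue
                key = SubgroupKey(man, sex, float(hs), float(lo), float(hi))
                n_pat = len(cell)
                n_ev = int(cell["revised"].sum())
                fit = stratum_fit
                flagged = False
                if n_ev < min_events or fit is None or not fit.converged:
                    fit = parent_fit
                    flagged = True
                if fit is None or not fit.converged:
                    raise ValueError(
                        f"no usable fit for subgroup {key}; too few events at "
                        "every stratification level"
                    )
                dec = classify_subgroup(
                    fit, key, threshold, horizon, n_patients=n_pat, n_events=n_ev
                )
                dec.flagged = flagged
                decisions.append(dec)
    return decisions


@dataclass
class DichotomyResult:
    within: pd.DataFrame
    not_within: pd.DataFrame
    summary: pd.DataFrame  # per-manufacturer counts and proportion within

    @property
    def proportion_within(self) -> float:
        total = len(self.within) + len(self.not_within)
        return len(self.within) / total if total else float("nan")


def dichotomize(
    registry: pd.DataFrame, decisions: Sequence[BenchmarkDecision]
) -> DichotomyResult:
    """Partition RS registry records into within / not-within pools.

    Every record must map to exactly one decided subgroup; an unmapped
    record raises an error naming the offending covariate combination.
    """
    rs = registry[registry["device_class"] == "RS"].reset_index(drop=True)
    lookup: Dict[Tuple[str, str, float, float, float], bool] = {}
    bands_by_group: Dict[Tuple[str, str, float], List[Tuple[float, float]]] = {}
    for dec in decisions:
        k = dec.subgroup
        lookup[(k.manufacturer, k.sex, k.head_size, k.age_lo, k.age_hi)] = dec.within
        bands_by_group.setdefault((k.manufacturer, k.sex, k.head_size), []).append(
            (k.age_lo, k.age_hi)
        )

    within_mask = np.zeros(len(rs), dtype=bool)
    for i, row in enumerate(rs.itertuples()):
        group = (row.manufacturer, row.sex, float(row.head_size))
        bands = bands_by_group.get(group)
        band = _band_for(float(row.age_at_primary), bands) if bands else None
        if band is None:
            raise ValueError(
                "no benchmark decision covers record with "
                f"manufacturer={row.manufacturer!r}, sex={row.sex!r}, "
                f"head_size={row.head_size}, age={row.age_at_primary}"
            )
        within_mask[i] = lookup[(group[0], group[1], group[2], band[0], band[1])]

    within = rs.loc[within_mask].reset_index(drop=True)
    not_within = rs.loc[~within_mask].reset_index(drop=True)
    summary = (
        pd.DataFrame(
            {
                "manufacturer": rs["manufacturer"],
                "within": within_mask,
            }
        )
        .groupby("manufacturer")
        .agg(n=("within", "size"), n_within=("within", "sum"))
        .reset_index()
    )
    summary["proportion_within"] = summary["n_within"] / summary["n"]
    return DichotomyResult(within=within, not_within=not_within, summary=summary)


def decisions_to_frame(decisions: Sequence[BenchmarkDecision]) -> pd.DataFrame:
    """Flat export: one row per subgroup decision."""
    return pd.DataFrame(
        [
            {
                "manufacturer": d.subgroup.manufacturer,
                "sex": d.subgroup.sex,
                "head_size": d.subgroup.head_size,
                "age_lo": d.subgroup.age_lo,
                "age_hi": d.subgroup.age_hi,
                "predicted_10y_revision": d.predicted_10y_revision,
                "within": d.within,
                "n_patients": d.n_patients,
                "n_events": d.n_events,
                "flagged": d.flagged,
                "extrapolated": d.extrapolated,
            }
            for d in decisions
        ]
    )
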