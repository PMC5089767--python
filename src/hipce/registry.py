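"""Synthetic joint-registry cohorts, registry filtering and life tables.

The generator produces individual patient records shaped like a national
implant registry extract: covariates, staggered entry over a fixed
recruitment window, event times drawn from a known parametric hazard and
administrative censoring at the window close.  Because the true hazard is
known, every downstream estimator can be validated against analytic truth.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .families import get_family, simulate_event_times

__all__ = [
    "ConfigurationError",
    "PatientRecord",
    "HazardSpec",
    "CohortSpec",
    "FilterRules",
    "FilterResult",
    "LifeTable",
    "generate_registry",
    "filter_registry",
    "make_life_table",
    "write_registry_csv",
    "read_registry_csv",
]

MANUFACTURERS = (
    "BirminghamHip",
    "Biomet",
    "Centerpulse",
    "Corin",
    "Finsbury",
    "WrightUK",
    "Other",
)
RS_HEAD_SIZES = tuple(range(38, 60, 2))
THR_CATEGORIES = ("CeMoP", "CeCoP", "CeLCoC", "none")

REGISTRY_COLUMNS = [
    "patient_id",
    "age_at_primary",
    "sex",
    "asa_grade",
    "manufacturer",
    "head_size",
    "device_class",
    "thr_category",
    "entry_time",
    "followup_time",
    "revised",
]


class ConfigurationError(ValueError):
    """Raised when a cohort or filter specification is invalid."""


@dataclass(frozen=True)
class PatientRecord:
    """One registry row."""

    patient_id: str
    age_at_primary: int
    sex: str
    asa_grade: int
    manufacturer: str
    head_size: Optional[int]
    device_class: str
    thr_category: str
    entry_time: float
    followup_time: float
    revised: int


@dataclass
class HazardSpec:
    """True time-to-revision hazard for one device class.

    ``log_hr`` maps covariate keys to log hazard ratios.  Supported keys:
    ``female``, ``asa_2``, ``asa_3plus``, ``head_size_minus_50``,
    ``age_minus_55``, ``manufacturer:<Name>``, ``thr_category:<Name>``, or
    any numeric registry column name.
    """

    family: str
    params: Dict[str, float]
    log_hr: Dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        try:
            get_family(self.family).validate(self.params)
        except ValueError as exc:
            raise ConfigurationError(f"hazard ({self.family}): {exc}") from exc
        for key, val in self.log_hr.items():
            if not np.isfinite(val):
                raise ConfigurationError(f"hazard log_hr[{key!r}] not finite")


def _default_head_size_probs() -> Dict[str, Dict[int, float]]:
    male = {38: 0.01, 40: 0.01, 42: 0.03, 44: 0.05, 46: 0.10, 48: 0.15,
            50: 0.25, 52: 0.20, 54: 0.12, 56: 0.06, 58: 0.02}
    female = {38: 0.08, 40: 0.12, 42: 0.22, 44: 0.25, 46: 0.18, 48: 0.10,
              50: 0.04, 52: 0.01, 54: 0.0, 56: 0.0, 58: 0.0}
    return {"male": male, "female": female}


def _default_age_band_probs() -> Dict[Tuple[int, int], float]:
    return {
        (35, 40): 0.05,
        (40, 45): 0.12,
        (45, 50): 0.20,
        (50, 55): 0.26,
        (55, 60): 0.22,
        (60, 65): 0.11,
        (65, 70): 0.04,
    }


@dataclass
class CohortSpec:
    """Full recipe for a synthetic registry cohort."""

    n_patients: int
    registry_window: float = 9.75
    seed: Optional[int] = None
    sex_probs: Dict[str, float] = field(
        default_factory=lambda: {"male": 0.74, "female": 0.26}
    )
    asa_probs: Dict[int, float] = field(
        default_factory=lambda: {1: 0.40, 2: 0.57, 3: 0.03}
    )
    device_class_probs: Dict[str, float] = field(
        default_factory=lambda: {"RS": 1.0, "THR": 0.0}
    )
    manufacturer_probs: Dict[str, float] = field(
        default_factory=lambda: {
            "BirminghamHip": 0.54,
            "Biomet": 0.08,
            "Centerpulse": 0.07,
            "Corin": 0.09,
            "Finsbury": 0.08,
            "WrightUK": 0.14,
        }
    )
    thr_category_probs: Dict[str, float] = field(
        default_factory=lambda: {"CeMoP": 0.60, "CeCoP": 0.25, "CeLCoC": 0.15}
    )
    head_size_probs: Dict[str, Dict[int, float]] = field(
        default_factory=_default_head_size_probs
    )
    age_band_probs: Dict[Tuple[int, int], float] = field(
        default_factory=_default_age_band_probs
    )
    hazards: Dict[str, HazardSpec] = field(
        default_factory=lambda: {
            "RS": HazardSpec(
                family="bathtub",
                params={
                    "shape_early": 0.6,
                    "scale_early": 1200.0,
                    "shape_late": 2.2,
                    "scale_late": 55.0,
                },
                log_hr={"female": 0.7, "head_size_minus_50": -0.18},
            ),
            "THR": HazardSpec(
                family="weibull", params={"shape": 1.1, "scale": 180.0}
            ),
        }
    )
    loss_to_followup_rate: float = 0.0
    # Optional background-death hazard; when set, simulated death times act
    # as additional censoring (death-before-revision treated as censored).
    death_hazard: Optional[HazardSpec] = None

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ConfigurationError("n_patients must be positive")
        if self.registry_window <= 0:
            raise ConfigurationError("registry_window must be positive")
        if self.loss_to_followup_rate < 0:
            raise ConfigurationError("loss_to_followup_rate must be >= 0")
        for name in (
            "sex_probs",
            "asa_probs",
            "device_class_probs",
            "manufacturer_probs",
            "thr_category_probs",
            "age_band_probs",
        ):
            probs = getattr(self, name)
            total = float(sum(probs.values()))
            if not math.isclose(total, 1.0, abs_tol=1e-8):
                raise ConfigurationError(f"{name} must sum to 1 (got {total:g})")
            if any(p < 0 for p in probs.values()):
                raise ConfigurationError(f"{name} contains a negative proportion")
        for sex, probs in self.head_size_probs.items():
            total = float(sum(probs.values()))
            if not math.isclose(total, 1.0, abs_tol=1e-8):
                raise ConfigurationError(
                    f"head_size_probs[{sex!r}] must sum to 1 (got {total:g})"
                )
        for cls, spec in self.hazards.items():
            if cls not in ("RS", "THR"):
                raise ConfigurationError(f"hazards key {cls!r} not a device class")
            spec.validate()
        if self.death_hazard is not None:
            self.death_hazard.validate()


def _choice(rng, probs: Mapping, size: int) -> np.ndarray:
    keys = list(probs.keys())
    p = np.asarray([probs[k] for k in keys], dtype=float)
    p = p / p.sum()
    idx = rng.choice(len(keys), size=size, p=p)
    return np.asarray([keys[i] for i in idx], dtype=object)


def resolve_covariate(frame: pd.DataFrame, key: str) -> np.ndarray:
    """Map a log-HR key to a numeric per-patient covariate value."""
    if key == "female":
        return (frame["sex"] == "female").to_numpy(dtype=float)
    if key == "male":
        return (frame["sex"] == "male").to_numpy(dtype=float)
    if key == "asa_2":
        return (frame["asa_grade"] == 2).to_numpy(dtype=float)
    if key == "asa_3plus":
        return (frame["asa_grade"] >= 3).to_numpy(dtype=float)
    if key == "head_size_minus_50":
        return (frame["head_size"].fillna(50.0) - 50.0).to_numpy(dtype=float)
    if key == "age_minus_55":
        return (frame["age_at_primary"] - 55.0).to_numpy(dtype=float)
    if key.startswith("manufacturer:"):
        return (frame["manufacturer"] == key.split(":", 1)[1]).to_numpy(dtype=float)
    if key.startswith("thr_category:"):
        return (frame["thr_category"] == key.split(":", 1)[1]).to_numpy(dtype=float)
    if key in frame.columns:
        return pd.to_numeric(frame[key]).fillna(0.0).to_numpy(dtype=float)
    raise ConfigurationError(f"unknown covariate key {key!r} in hazard log_hr")


def generate_registry(spec: CohortSpec, seed: Optional[int] = None) -> pd.DataFrame:
    """Generate a synthetic registry table; deterministic for a fixed seed."""
    spec.validate()
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    n = spec.n_patients

    sex = _choice(rng, spec.sex_probs, n)
    asa = _choice(rng, spec.asa_probs, n).astype(int)
    device = _choice(rng, spec.device_class_probs, n)

    bands = list(spec.age_band_probs.keys())
    band_idx = rng.choice(
        len(bands),
        size=n,
        p=np.asarray(list(spec.age_band_probs.values())) / sum(spec.age_band_probs.values()),
    )
    age = np.array(
        [rng.integers(bands[i][0], bands[i][1]) for i in band_idx], dtype=int
    )

    manufacturer = np.full(n, "Other", dtype=object)
    head_size = np.full(n, np.nan)
    thr_category = np.full(n, "none", dtype=object)
    is_rs = device == "RS"
    n_rs = int(is_rs.sum())
    if n_rs:
        manufacturer[is_rs] = _choice(rng, spec.manufacturer_probs, n_rs)
        for s in ("male", "female"):
            mask = is_rs & (sex == s)
            m = int(mask.sum())
            if m:
                head_size[mask] = _choice(
                    rng, spec.head_size_probs[s], m
                ).astype(float)
    n_thr = int((~is_rs).sum())
    if n_thr:
        thr_category[~is_rs] = _choice(rng, spec.thr_category_probs, n_thr)

    entry = rng.uniform(0.0, spec.registry_window, size=n)
    frame = pd.DataFrame(
        {
            "patient_id": [f"P{i:07d}" for i in range(n)],
            "age_at_primary": age,
            "sex": sex,
            "asa_grade": asa,
            "manufacturer": manufacturer,
            "head_size": head_size,
            "device_class": device,
            "thr_category": thr_category,
            "entry_time": entry,
        }
    )

    event_time = np.full(n, np.inf)
    for cls in ("RS", "THR"):
        mask = (device == cls).astype(bool)
        if not mask.any():
            continue
        spec_h = spec.hazards.get(cls)
        if spec_h is None:
            raise ConfigurationError(f"no hazard specified for device class {cls!r}")
        sub = frame.loc[mask]
        lp = np.zeros(int(mask.sum()))
        for key, coef in spec_h.log_hr.items():
            lp += coef * resolve_covariate(sub, key)
        event_time[mask] = simulate_event_times(
            spec_h.family, spec_h.params, rng=rng, linear_predictor=lp
        )

    censor = spec.registry_window - entry
    if spec.loss_to_followup_rate > 0:
        ltf = rng.exponential(1.0 / spec.loss_to_followup_rate, size=n)
        censor = np.minimum(censor, ltf)
    if spec.death_hazard is not None:
        death = simulate_event_times(
            spec.death_hazard.family,
            spec.death_hazard.params,
            rng=rng,
            linear_predictor=np.zeros(n),
        )
        censor = np.minimum(censor, death)

    revised = (event_time < censor).astype(int)
    followup = np.where(revised == 1, event_time, censor)
    followup = np.maximum(followup, 1e-9)  # followup_time must stay positive
    frame["followup_time"] = followup
    frame["revised"] = revised
    return frame[REGISTRY_COLUMNS]


@dataclass
class FilterRules:
    """Registry inclusion/exclusion rules, applied in declaration order."""

    allowed_asa: Optional[Iterable[int]] = None
    excluded_manufacturers: Optional[Iterable[str]] = None
    allowed_device_classes: Optional[Iterable[str]] = None


@dataclass
class FilterResult:
    records: pd.DataFrame
    removed: Dict[str, int]


def filter_registry(records: pd.DataFrame, rules: FilterRules) -> FilterResult:
    """Apply inclusion rules, reporting the count removed per rule."""
    out = records
    removed: Dict[str, int] = {}
    if rules.allowed_asa is not None:
        allowed = set(rules.allowed_asa)
        keep = out["asa_grade"].isin(allowed)
        removed["asa_grade"] = int((~keep).sum())
        out = out.loc[keep]
    if rules.excluded_manufacturers is not None:
        excluded = set(rules.excluded_manufacturers)
        keep = ~out["manufacturer"].isin(excluded)
        removed["manufacturer"] = int((~keep).sum())
        out = out.loc[keep]
    if rules.allowed_device_classes is not None:
        allowed = set(rules.allowed_device_classes)
        keep = out["device_class"].isin(allowed)
        removed["device_class"] = int((~keep).sum())
        out = out.loc[keep]
    if out.empty:
        warnings.warn("filter_registry produced an empty registry", stacklevel=2)
    return FilterResult(records=out.reset_index(drop=True), removed=removed)


class LifeTable:
    """Annual death probabilities qx by sex and integer age."""

    def __init__(self, frame: pd.DataFrame):
        required = {"sex", "age", "qx"}
        if not required.issubset(frame.columns):
            raise ConfigurationError(f"life table needs columns {sorted(required)}")
        if ((frame["qx"] < 0) | (frame["qx"] > 1)).any():
            raise ConfigurationError("life table qx values must lie in [0, 1]")
        self.frame = frame.reset_index(drop=True)
        self._lookup = {
            (row.sex, int(row.age)): float(row.qx) for row in frame.itertuples()
        }
        self._max_age = {
            s: int(frame.loc[frame["sex"] == s, "age"].max())
            for s in frame["sex"].unique()
        }

    def qx(self, sex: str, age: int) -> float:
        age = int(age)
        max_age = self._max_age.get(sex)
        if max_age is None:
            raise KeyError(f"life table has no entries for sex {sex!r}")
        if age > max_age:
            return 1.0
        try:
            return self._lookup[(sex, age)]
        except KeyError:
            raise KeyError(f"life table missing age {age} for sex {sex!r}") from None

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        return cls(pd.read_csv(path))

    @classmethod
    def concat(cls, tables: Sequence["LifeTable"]) -> "LifeTable":
        return cls(pd.concat([t.frame for t in tables], ignore_index=True))


def make_life_table(
    sex: str,
    makeham_a: float,
    gompertz_b: float,
    gompertz_c: float,
    max_age: int = 100,
    min_age: int = 30,
) -> LifeTable:
    """Gompertz–Makeham life table: qx = 1 - exp(-(a + b*exp(c*age)))."""
    if makeham_a < 0 or gompertz_b < 0 or gompertz_c < 0:
        raise ConfigurationError("life table parameters must be non-negative")
    if max_age > 120:
        raise ConfigurationError("max_age must not exceed 120")
    ages = np.arange(min_age, max_age + 1)
    hazard = makeham_a + gompertz_b * np.exp(gompertz_c * ages)
    qx = np.clip(1.0 - np.exp(-hazard), 0.0, 1.0)
    return LifeTable(pd.DataFrame({"sex": sex, "age": ages, "qx": qx}))


def write_registry_csv(frame: pd.DataFrame, path) -> None:
    """RFC-4180 CSV; missing head size written as an empty field."""
    frame.to_csv(path, index=False)


def read_registry_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in REGISTRY_COLUMNS if c not in frame.columns]
    if missing:
        raise ConfigurationError(f"registry CSV missing columns: {missing}")
    return frame[REGISTRY_COLUMNS]
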