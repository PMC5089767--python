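"""Parametric baseline hazard families.

Every family exposes the baseline cumulative hazard ``H0(t)``, the log
baseline hazard ``log h0(t)`` and the inverse of ``H0`` (used for inverse
transform sampling).  Covariates act multiplicatively on the cumulative
hazard, ``H(t | x) = H0(t) * exp(x @ beta)``, so a single exponential draw
``E`` maps to an event time via ``H0(T) = E / exp(x @ beta)``.

Natural parameters are stored as plain dicts; an internal unconstrained
vector parameterisation (log / logit transforms) is used by the optimiser.
"""

from __future__ import annotations

import math
from typing import Dict, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = ["get_family", "available_families", "simulate_event_times"]

_EPS = 1e-300


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _expit(x: np.ndarray | float):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


class Family:
    """Base class; subclasses define the closed forms."""

    name: str = ""
    param_names: Sequence[str] = ()

    def to_internal(self, params: Dict[str, float]) -> np.ndarray:
        raise NotImplementedError

    def from_internal(self, vec: np.ndarray) -> Dict[str, float]:
        raise NotImplementedError

    def cum_hazard(self, t, params):
        raise NotImplementedError

    def log_hazard(self, t, params):
        raise NotImplementedError

    def inverse_cum_hazard(self, target, params):
        """Solve H0(T) = target for T (vectorised; inf when unreachable)."""
        raise NotImplementedError

    def init_params(self, t, d) -> Dict[str, float]:
        """Crude starting values from event/censoring data."""
        raise NotImplementedError

    def validate(self, params: Dict[str, float]) -> None:
        for name in self.param_names:
            if name not in params:
                raise ValueError(f"{self.name}: missing parameter {name!r}")
            if not np.isfinite(params[name]):
                raise ValueError(f"{self.name}: parameter {name!r} not finite")


def _exp_scale(t, d) -> float:
    events = max(float(np.sum(d)), 1.0)
    return float(np.sum(t)) / events


class Weibull(Family):
    name = "weibull"
    param_names = ("shape", "scale")

    def to_internal(self, params):
        return np.array([math.log(params["shape"]), math.log(params["scale"])])

    def from_internal(self, vec):
        return {"shape": float(np.exp(vec[0])), "scale": float(np.exp(vec[1]))}

    def cum_hazard(self, t, params):
        k, lam = params["shape"], params["scale"]
        return (np.asarray(t, dtype=float) / lam) ** k

    def log_hazard(self, t, params):
        k, lam = params["shape"], params["scale"]
        t = np.asarray(t, dtype=float)
        return math.log(k / lam) + (k - 1.0) * (np.log(t) - math.log(lam))

    def inverse_cum_hazard(self, target, params):
        k, lam = params["shape"], params["scale"]
        return lam * np.asarray(target, dtype=float) ** (1.0 / k)

    def init_params(self, t, d):
        return {"shape": 1.0, "scale": _exp_scale(t, d)}

    def validate(self, params):
        super().validate(params)
        if params["shape"] <= 0 or params["scale"] <= 0:
            raise ValueError("weibull: shape and scale must be positive")


class Gompertz(Family):
    """h0(t) = rate * exp(shape * t); shape may be negative."""

    name = "gompertz"
    param_names = ("rate", "shape")

    def to_internal(self, params):
        return np.array([math.log(params["rate"]), params["shape"]])

    def from_internal(self, vec):
        return {"rate": float(np.exp(vec[0])), "shape": float(vec[1])}

    def cum_hazard(self, t, params):
        b, c = params["rate"], params["shape"]
        t = np.asarray(t, dtype=float)
        if abs(c) < 1e-12:
            return b * t
        return b / c * np.expm1(c * t)

    def log_hazard(self, t, params):
        b, c = params["rate"], params["shape"]
        return math.log(b) + c * np.asarray(t, dtype=float)

    def inverse_cum_hazard(self, target, params):
        b, c = params["rate"], params["shape"]
        target = np.asarray(target, dtype=float)
        if abs(c) < 1e-12:
            return target / b
        arg = 1.0 + c * target / b
        out = np.full(target.shape if target.ndim else (), np.inf, dtype=float)
        ok = arg > 0
        out = np.where(ok, np.log(np.where(ok, arg, 1.0)) / c, np.inf)
        return out

    def init_params(self, t, d):
        return {"rate": 1.0 / _exp_scale(t, d), "shape": 0.01}

    def validate(self, params):
        super().validate(params)
        if params["rate"] <= 0:
            raise ValueError("gompertz: rate must be positive")


class LogLogistic(Family):
    name = "loglogistic"
    param_names = ("scale", "shape")

    def to_internal(self, params):
        return np.array([math.log(params["scale"]), math.log(params["shape"])])

    def from_internal(self, vec):
        return {"scale": float(np.exp(vec[0])), "shape": float(np.exp(vec[1]))}

    def cum_hazard(self, t, params):
        a, b = params["scale"], params["shape"]
        return np.log1p((np.asarray(t, dtype=float) / a) ** b)

    def log_hazard(self, t, params):
        a, b = params["scale"], params["shape"]
        t = np.asarray(t, dtype=float)
        z = (t / a) ** b
        return math.log(b / a) + (b - 1.0) * (np.log(t) - math.log(a)) - np.log1p(z)

    def inverse_cum_hazard(self, target, params):
        a, b = params["scale"], params["shape"]
        return a * np.expm1(np.asarray(target, dtype=float)) ** (1.0 / b)

    def init_params(self, t, d):
        ev = t[np.asarray(d, dtype=bool)]
        med = float(np.median(ev)) if ev.size else _exp_scale(t, d)
        return {"scale": med, "shape": 1.0}

    def validate(self, params):
        super().validate(params)
        if params["scale"] <= 0 or params["shape"] <= 0:
            raise ValueError("loglogistic: scale and shape must be positive")


class GenGamma(Family):
    """Generalised gamma (Stacy), positive power; wraps scipy.stats.gengamma."""

    name = "gengamma"
    param_names = ("a", "c", "scale")

    def to_internal(self, params):
        return np.array(
            [math.log(params["a"]), math.log(params["c"]), math.log(params["scale"])]
        )

    def from_internal(self, vec):
        return {
            "a": float(np.exp(vec[0])),
            "c": float(np.exp(vec[1])),
            "scale": float(np.exp(vec[2])),
        }

    def cum_hazard(self, t, params):
        return -stats.gengamma.logsf(t, params["a"], params["c"], scale=params["scale"])

    def log_hazard(self, t, params):
        a, c, s = params["a"], params["c"], params["scale"]
        return stats.gengamma.logpdf(t, a, c, scale=s) - stats.gengamma.logsf(
            t, a, c, scale=s
        )

    def inverse_cum_hazard(self, target, params):
        a, c, s = params["a"], params["c"], params["scale"]
        sf = np.exp(-np.asarray(target, dtype=float))
        return stats.gengamma.isf(sf, a, c, scale=s)

    def init_params(self, t, d):
        return {"a": 1.0, "c": 1.0, "scale": _exp_scale(t, d)}

    def validate(self, params):
        super().validate(params)
        if min(params["a"], params["c"], params["scale"]) <= 0:
            raise ValueError("gengamma: all parameters must be positive")


class Bathtub(Family):
    """Additive two-Weibull hazard: a decreasing early component
    (shape_early < 1) plus an increasing late component (shape_late > 1).
    """

    name = "bathtub"
    param_names = ("shape_early", "scale_early", "shape_late", "scale_late")

    def to_internal(self, params):
        return np.array(
            [
                _logit(params["shape_early"]),
                math.log(params["scale_early"]),
                math.log(params["shape_late"] - 1.0),
                math.log(params["scale_late"]),
            ]
        )

    def from_internal(self, vec):
        return {
            "shape_early": float(_expit(vec[0])),
            "scale_early": float(np.exp(vec[1])),
            "shape_late": float(1.0 + np.exp(vec[2])),
            "scale_late": float(np.exp(vec[3])),
        }

    def _components(self, t, params):
        t = np.asarray(t, dtype=float)
        k1, l1 = params["shape_early"], params["scale_early"]
        k2, l2 = params["shape_late"], params["scale_late"]
        h1 = k1 / l1 * (t / l1) ** (k1 - 1.0)
        h2 = k2 / l2 * (t / l2) ** (k2 - 1.0)
        return h1, h2

    def cum_hazard(self, t, params):
        t = np.asarray(t, dtype=float)
        k1, l1 = params["shape_early"], params["scale_early"]
        k2, l2 = params["shape_late"], params["scale_late"]
        return (t / l1) ** k1 + (t / l2) ** k2

    def log_hazard(self, t, params):
        h1, h2 = self._components(t, params)
        return np.log(h1 + h2 + _EPS)

    def hazard_components(self, t, params):
        """(early, late) hazard contributions — used to inspect dominance."""
        return self._components(t, params)

    def inverse_cum_hazard(self, target, params):
        target = np.atleast_1d(np.asarray(target, dtype=float))
        out = np.empty_like(target)
        for i, tgt in enumerate(target):
            if tgt <= 0:
                out[i] = 0.0
                continue
            hi = 1.0
            while self.cum_hazard(hi, params) < tgt and hi < 1e8:
                hi *= 2.0
            if hi >= 1e8:
                out[i] = np.inf
                continue
            out[i] = optimize.brentq(
                lambda x: self.cum_hazard(x, params) - tgt, 1e-12, hi
            )
        return out if out.size > 1 else float(out[0])

    def init_params(self, t, d):
        s0 = _exp_scale(t, d)
        return {
            "shape_early": 0.5,
            "scale_early": 4.0 * s0,
            "shape_late": 2.0,
            "scale_late": 2.0 * s0,
        }

    def validate(self, params):
        super().validate(params)
        if not 0 < params["shape_early"] < 1:
            raise ValueError("bathtub: shape_early must lie in (0, 1)")
        if params["shape_late"] <= 1:
            raise ValueError("bathtub: shape_late must exceed 1")
        if params["scale_early"] <= 0 or params["scale_late"] <= 0:
            raise ValueError("bathtub: scales must be positive")


class Zero(Family):
    """Degenerate zero hazard (no events ever); generator-only."""

    name = "zero"
    param_names = ()

    def to_internal(self, params):
        return np.array([])

    def from_internal(self, vec):
        return {}

    def cum_hazard(self, t, params):
        return np.zeros_like(np.asarray(t, dtype=float))

    def log_hazard(self, t, params):
        return np.full_like(np.asarray(t, dtype=float), -np.inf)

    def inverse_cum_hazard(self, target, params):
        target = np.asarray(target, dtype=float)
        return np.where(target > 0, np.inf, 0.0)

    def init_params(self, t, d):
        return {}


_FAMILIES: Dict[str, Family] = {
    f.name: f for f in (Weibull(), Gompertz(), LogLogistic(), GenGamma(), Bathtub(), Zero())
}


def available_families():
    return tuple(name for name in _FAMILIES if name != "zero")


def get_family(name: str) -> Family:
    try:
        return _FAMILIES[name]
    except KeyError:
        raise ValueError(
            f"unknown hazard family {name!r}; choose from {sorted(_FAMILIES)}"
        ) from None


def simulate_event_times(family, params, n=None, rng=None, linear_predictor=None):
    """Inverse-transform sample event times from ``H0(t) * exp(lp)``.

    Either ``n`` (with optional scalar linear predictor) or a per-subject
    ``linear_predictor`` array must be given.
    """
    fam = get_family(family) if isinstance(family, str) else family
    fam.validate(params)
    if rng is None:
        rng = np.random.default_rng()
    if linear_predictor is not None:
        lp = np.asarray(linear_predictor, dtype=float)
        n = lp.shape[0]
    else:
        lp = np.zeros(n)
    e = rng.exponential(size=n)
    target = e / np.exp(lp)
    return np.asarray(fam.inverse_cum_hazard(target, params), dtype=float)
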