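"""Time-to-revision estimation and extrapolation.

Three routes are provided:

* :func:`kaplan_meier` — product-limit estimate with Greenwood variance and
  log(-log) confidence bounds;
* :func:`fit_royston_parmar` — restricted cubic spline on the log cumulative
  hazard as a function of log time, with proportional covariate effects
  (with one degree of freedom this is exactly a Weibull model);
* :func:`fit_parametric` — maximum likelihood for Weibull, Gompertz,
  log-logistic, generalised gamma and an additive two-Weibull "bathtub"
  hazard, sharing the proportional-hazards covariate convention.

Fitted models convert to annual conditional revision probabilities for the
cohort model via :func:`annual_transition_probs`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .families import get_family

__all__ = [
    "ConvergenceError",
    "KMEstimate",
    "SurvivalFit",
    "AnnualRevisionSchedule",
    "kaplan_meier",
    "fit_royston_parmar",
    "fit_parametric",
    "predict_cumulative_revision",
    "annual_transition_probs",
]


class ConvergenceError(RuntimeError):
    """Raised when prediction is requested from a non-converged fit."""


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass
class KMEstimate:
    times: np.ndarray
    survival: np.ndarray
    variance: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    at_risk: np.ndarray
    n: int
    n_events: int

    def survival_at(self, t: float) -> float:
        """Step-function value S(t); S(0) = 1 by definition."""
        if t < 0:
            raise ValueError("t must be non-negative")
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.times,
                "survival": self.survival,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "at_risk": self.at_risk,
            }
        )


def kaplan_meier(times, events, alpha: float = 0.05) -> KMEstimate:
    """Product-limit estimator with Greenwood variance and log(-log) CI."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.shape != events.shape:
        raise ValueError("times and events must have the same shape")
    if (times <= 0).any():
        raise ValueError("times must be positive")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("events must be 0/1")
    n = times.size
    if events.sum() == 0:
        warnings.warn("all observations censored; S(t) = 1 everywhere", stacklevel=2)
        empty = np.array([])
        return KMEstimate(empty, empty, empty, empty, empty, empty, n, 0)

    order = np.argsort(times, kind="stable")
    t_sorted, e_sorted = times[order], events[order]
    event_times = np.unique(t_sorted[e_sorted == 1])
    at_risk = np.array([(t_sorted >= t).sum() for t in event_times], dtype=float)
    d = np.array(
        [((t_sorted == t) & (e_sorted == 1)).sum() for t in event_times], dtype=float
    )
    surv = np.cumprod(1.0 - d / at_risk)
    green_terms = np.cumsum(d / (at_risk * (at_risk - d + (at_risk == d))))
    variance = surv**2 * green_terms

    z = stats.norm.ppf(1.0 - alpha / 2.0)
    lower = np.zeros_like(surv)
    upper = np.ones_like(surv)
    with np.errstate(divide="ignore", invalid="ignore"):
        ok = (surv > 0) & (surv < 1)
        se_theta = np.sqrt(green_terms[ok]) / np.abs(np.log(surv[ok]))
        lower[ok] = surv[ok] ** np.exp(z * se_theta)
        upper[ok] = surv[ok] ** np.exp(-z * se_theta)
    lower[surv == 0] = 0.0
    upper[surv == 0] = 0.0
    return KMEstimate(
        times=event_times,
        survival=surv,
        variance=variance,
        ci_lower=np.clip(lower, 0.0, 1.0),
        ci_upper=np.clip(upper, 0.0, 1.0),
        at_risk=at_risk,
        n=n,
        n_events=int(events.sum()),
    )


# ---------------------------------------------------------------------------
# Restricted cubic spline basis on log time


def _rcs_basis(u: np.ndarray, knots: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Basis [1, u, v_1(u), ...] and its derivative wrt u.

    Natural-spline construction: cubic between boundary knots, linear
    outside them.
    """
    u = np.asarray(u, dtype=float)
    n_int = len(knots) - 2
    Z = np.empty((u.size, 2 + max(n_int, 0)))
    dZ = np.zeros_like(Z)
    Z[:, 0] = 1.0
    Z[:, 1] = u
    dZ[:, 1] = 1.0
    if n_int > 0:
        kmin, kmax = knots[0], knots[-1]
        span = kmax - kmin
        for j in range(n_int):
            kj = knots[j + 1]
            lam = (kmax - kj) / span
            p1 = np.clip(u - kj, 0, None)
            p2 = np.clip(u - kmin, 0, None)
            p3 = np.clip(u - kmax, 0, None)
            Z[:, 2 + j] = p1**3 - lam * p2**3 - (1 - lam) * p3**3
            dZ[:, 2 + j] = 3.0 * (p1**2 - lam * p2**2 - (1 - lam) * p3**2)
    return Z, dZ


def _rp_knots(log_event_times: np.ndarray, df: int) -> np.ndarray:
    """Boundary knots at the extremes, internal knots at equally spaced
    centiles of the uncensored log event times."""
    if df < 1:
        raise ValueError("df must be >= 1")
    qs = np.linspace(0, 100, df + 1)
    knots = np.percentile(log_event_times, qs)
    if np.any(np.diff(knots) <= 0):
        raise ValueError("degenerate knot sequence; reduce df")
    return knots


# ---------------------------------------------------------------------------
# Fit container


@dataclass
class SurvivalFit:
    """A fitted time-to-revision model able to predict S(t | x)."""

    family: str
    params: Dict[str, float]
    beta: Dict[str, float] = field(default_factory=dict)
    knots: Optional[np.ndarray] = None
    gammas: Optional[np.ndarray] = None
    log_likelihood: float = np.nan
    n: int = 0
    n_events: int = 0
    converged: bool = True
    params_se: Dict[str, float] = field(default_factory=dict)
    beta_se: Dict[str, float] = field(default_factory=dict)
    covariate_ranges: Dict[str, Tuple[float, float]] = field(default_factory=dict)

    @property
    def covariate_names(self) -> Tuple[str, ...]:
        return tuple(self.beta.keys())

    def _require_converged(self) -> None:
        if not self.converged:
            raise ConvergenceError(
                f"{self.family} fit did not converge; prediction refused"
            )

    def linear_predictor(self, covariate_values: Optional[Mapping[str, float]]) -> float:
        lp = 0.0
        cov = covariate_values or {}
        for name, coef in self.beta.items():
            if name not in cov:
                raise ValueError(f"missing covariate value for {name!r}")
            lp += coef * float(cov[name])
        return lp

    def cumulative_hazard(self, t, covariate_values=None) -> np.ndarray:
        self._require_converged()
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if (t < 0).any():
            raise ValueError("t must be non-negative")
        lp = self.linear_predictor(covariate_values)
        if self.family == "royston_parmar":
            H = np.zeros_like(t)
            pos = t > 0
            if pos.any():
                Z, _ = _rcs_basis(np.log(t[pos]), self.knots)
                H[pos] = np.exp(Z @ self.gammas + lp)
            return H
        fam = get_family(self.family)
        return fam.cum_hazard(t, self.params) * np.exp(lp)

    def predict_survival(self, t, covariate_values=None):
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        S = np.exp(-self.cumulative_hazard(t_arr, covariate_values))
        return S if np.ndim(t) else float(S[0])

    def predict_cumulative_revision(self, t, covariate_values=None):
        S = self.predict_survival(t, covariate_values)
        return 1.0 - S

    def is_extrapolated(self, covariate_values: Optional[Mapping[str, float]]) -> bool:
        """True when any covariate lies outside the fitted data range."""
        cov = covariate_values or {}
        for name, (lo, hi) in self.covariate_ranges.items():
            if name in cov and not (lo <= float(cov[name]) <= hi):
                return True
        return False

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "params": self.params,
            "beta": self.beta,
            "knots": None if self.knots is None else list(map(float, self.knots)),
            "gammas": None if self.gammas is None else list(map(float, self.gammas)),
            "log_likelihood": float(self.log_likelihood),
            "n": self.n,
            "n_events": self.n_events,
            "converged": self.converged,
            "params_se": self.params_se,
            "beta_se": self.beta_se,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "SurvivalFit":
        return cls(
            family=d["family"],
            params=dict(d.get("params", {})),
            beta=dict(d.get("beta", {})),
            knots=None if d.get("knots") is None else np.asarray(d["knots"]),
            gammas=None if d.get("gammas") is None else np.asarray(d["gammas"]),
            log_likelihood=d.get("log_likelihood", np.nan),
            n=d.get("n", 0),
            n_events=d.get("n_events", 0),
            converged=d.get("converged", True),
            params_se=dict(d.get("params_se", {})),
            beta_se=dict(d.get("beta_se", {})),
        )

    def export_curve(self, t, covariate_values=None) -> pd.DataFrame:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        S = self.predict_survival(t, covariate_values)
        return pd.DataFrame({"t": t, "survival": S})


# ---------------------------------------------------------------------------
# Generic optimisation helpers

_BIG = 1e12


def _safe(fun):
    def wrapped(x, *args):
        val = fun(x, *args)
        if not np.isfinite(val):
            return _BIG
        return val

    return wrapped


def _minimize_with_restarts(nll, x0, n_restarts: int = 5, rng_seed: int = 0):
    """L-BFGS-B from the base start plus perturbed restarts; best wins."""
    rng = np.random.default_rng(rng_seed)
    best = None
    starts = [np.asarray(x0, dtype=float)]
    starts += [
        np.asarray(x0, dtype=float) + rng.normal(0.0, 0.3, size=len(x0))
        for _ in range(n_restarts)
    ]
    for start in starts:
        try:
            res = optimize.minimize(
                nll,
                start,
                method="L-BFGS-B",
                options={"maxiter": 500, "ftol": 1e-13, "gtol": 1e-9},
            )
        except Exception:  # numerical blow-up in a restart is non-fatal
            continue
        if not np.isfinite(res.fun) or res.fun >= _BIG / 2:
            continue
        if best is None or res.fun < best.fun - 1e-10:
            best = res
        if best is not None and best.fun < _BIG / 2 and start is starts[0] and res.success:
            break  # base start converged cleanly; no need to perturb
    return best


def _num_hessian(f, x, eps: float = 1e-4) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    p = x.size
    H = np.empty((p, p))
    f0 = f(x)
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = eps
            ej = np.zeros(p); ej[j] = eps
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * eps * eps)
    if not np.isfinite(H).all():
        H = np.full((p, p), np.nan)
        np.fill_diagonal(H, 1.0 / eps)
        _ = f0
    return H


def _cov_from_hessian(nll, x) -> Optional[np.ndarray]:
    H = _num_hessian(nll, x)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None
    if not np.isfinite(cov).all():
        return None
    return cov


def _extract_data(records, covariates, time_col, event_col):
    if isinstance(records, pd.DataFrame):
        t = records[time_col].to_numpy(dtype=float)
        d = records[event_col].to_numpy(dtype=int)
        X = (
            records[list(covariates)].to_numpy(dtype=float)
            if covariates
            else None
        )
    else:
        t = np.asarray(records[0], dtype=float)
        d = np.asarray(records[1], dtype=int)
        X = None
        if covariates:
            raise ValueError("covariates require a DataFrame input")
    if (t <= 0).any():
        raise ValueError("follow-up times must be positive")
    return t, d, X


def _covariate_ranges(records, covariates):
    if not covariates or not isinstance(records, pd.DataFrame):
        return {}
    return {
        c: (float(records[c].min()), float(records[c].max())) for c in covariates
    }


# ---------------------------------------------------------------------------
# Parametric maximum likelihood (proportional hazards on H0)


def fit_parametric(
    records,
    family: str,
    covariates: Sequence[str] = (),
    time_col: str = "followup_time",
    event_col: str = "revised",
    n_restarts: int = 5,
    init: Optional[Dict[str, float]] = None,
) -> SurvivalFit:
    """Maximum-likelihood fit of a parametric hazard family.

    Covariates act proportionally on the cumulative hazard.  Requires at
    least 10 events.
    """
    fam = get_family(family)
    t, d, X = _extract_data(records, covariates, time_col, event_col)
    n_events = int(d.sum())
    if n_events == 0:
        raise ValueError("no events in the data; fit refused")
    if n_events < 10:
        raise ValueError(f"need >= 10 events to fit (got {n_events})")

    p_fam = len(fam.param_names)
    x0_fam = fam.to_internal(init or fam.init_params(t, d))
    n_beta = 0 if X is None else X.shape[1]
    x0 = np.concatenate([x0_fam, np.zeros(n_beta)])

    def nll(vec):
        params = fam.from_internal(vec[:p_fam])
        lp = X @ vec[p_fam:] if X is not None else 0.0
        with np.errstate(all="ignore"):
            H = fam.cum_hazard(t, params) * np.exp(lp)
            logh = fam.log_hazard(t, params) + lp
            ll = float(np.sum(d * logh) - np.sum(H))
        if not np.isfinite(ll):
            return _BIG
        return -ll

    res = _minimize_with_restarts(_safe(nll), x0, n_restarts=n_restarts)
    converged = res is not None and np.isfinite(res.fun) and res.fun < _BIG / 2
    if not converged:
        return SurvivalFit(
            family=family,
            params=fam.from_internal(x0[:p_fam]),
            converged=False,
            n=t.size,
            n_events=n_events,
        )

    vec = res.x
    params = fam.from_internal(vec[:p_fam])
    beta = {c: float(b) for c, b in zip(covariates, vec[p_fam:])}

    params_se: Dict[str, float] = {}
    beta_se: Dict[str, float] = {}
    cov = _cov_from_hessian(_safe(nll), vec)
    if cov is not None:
        # delta method through the internal -> natural reparameterisation
        eps = 1e-6
        J = np.zeros((p_fam, p_fam))
        for i in range(p_fam):
            e = np.zeros(p_fam); e[i] = eps
            hi = fam.from_internal(vec[:p_fam] + e)
            lo = fam.from_internal(vec[:p_fam] - e)
            for j, name in enumerate(fam.param_names):
                J[j, i] = (hi[name] - lo[name]) / (2 * eps)
        nat_cov = J @ cov[:p_fam, :p_fam] @ J.T
        diag = np.diag(nat_cov)
        for j, name in enumerate(fam.param_names):
            if diag[j] > 0:
                params_se[name] = float(np.sqrt(diag[j]))
        for j, c in enumerate(covariates):
            v = cov[p_fam + j, p_fam + j]
            if v > 0:
                beta_se[c] = float(np.sqrt(v))

    return SurvivalFit(
        family=family,
        params=params,
        beta=beta,
        log_likelihood=-float(res.fun),
        n=t.size,
        n_events=n_events,
        converged=True,
        params_se=params_se,
        beta_se=beta_se,
        covariate_ranges=_covariate_ranges(records, covariates),
    )


# ---------------------------------------------------------------------------
# Royston-Parmar flexible parametric model


def fit_royston_parmar(
    records,
    df: int = 3,
    covariates: Sequence[str] = (),
    time_col: str = "followup_time",
    event_col: str = "revised",
    n_restarts: int = 5,
) -> SurvivalFit:
    """Restricted cubic spline on log H(t) against log t.

    ``df`` spline degrees of freedom give ``df - 1`` internal knots placed
    at equally spaced centiles of the uncensored log event times, with
    boundary knots at the extremes.  ``df = 1`` is exactly a Weibull model
    in a different parameterisation.
    """
    t, d, X = _extract_data(records, covariates, time_col, event_col)
    n_events = int(d.sum())
    if n_events == 0:
        raise ValueError("no events in the data; fit refused")
    if n_events < 10:
        raise ValueError(f"need >= 10 events to fit (got {n_events})")

    u = np.log(t)
    knots = _rp_knots(u[d == 1], df)
    Z, dZ = _rcs_basis(u, knots)
    n_gamma = Z.shape[1]
    n_beta = 0 if X is None else X.shape[1]
    dvec = d.astype(float)

    def nll(vec):
        gam = vec[:n_gamma]
        lp = X @ vec[n_gamma:] if X is not None else 0.0
        s = Z @ gam
        ds = dZ @ gam
        eta = s + lp
        with np.errstate(all="ignore"):
            H = np.exp(eta)
            ds_ev = ds[d == 1]
            if np.any(ds_ev <= 0):
                # hazard must stay positive at event times
                return _BIG / 2 + 1e6 * float(np.sum(np.clip(-ds_ev, 0, None) + 1))
            ll = float(
                np.sum(dvec * (eta + np.where(d == 1, np.log(np.clip(ds, 1e-300, None)), 0.0) - u))
                - np.sum(H)
            )
        if not np.isfinite(ll):
            return _BIG
        return -ll

    # initialise from a Weibull fit: log H = k*log t - k*log lambda
    try:
        wb = fit_parametric(
            records, "weibull", covariates, time_col, event_col, n_restarts=2
        )
        k = wb.params["shape"]
        lam = wb.params["scale"]
        gam0 = np.zeros(n_gamma)
        gam0[0] = -k * np.log(lam)
        gam0[1] = k
        beta0 = np.array([wb.beta.get(c, 0.0) for c in covariates])
    except Exception:
        gam0 = np.zeros(n_gamma)
        gam0[1] = 1.0
        beta0 = np.zeros(n_beta)
    x0 = np.concatenate([gam0, beta0])

    res = _minimize_with_restarts(_safe(nll), x0, n_restarts=n_restarts)
    converged = res is not None and np.isfinite(res.fun) and res.fun < _BIG / 4
    if not converged:
        return SurvivalFit(
            family="royston_parmar",
            params={},
            knots=knots,
            gammas=gam0,
            converged=False,
            n=t.size,
            n_events=n_events,
        )

    vec = res.x
    beta = {c: float(b) for c, b in zip(covariates, vec[n_gamma:])}
    beta_se: Dict[str, float] = {}
    params_se: Dict[str, float] = {}
    cov = _cov_from_hessian(_safe(nll), vec)
    if cov is not None:
        for j, c in enumerate(covariates):
            v = cov[n_gamma + j, n_gamma + j]
            if v > 0:
                beta_se[c] = float(np.sqrt(v))
        for j in range(n_gamma):
            v = cov[j, j]
            if v > 0:
                params_se[f"gamma{j}"] = float(np.sqrt(v))

    return SurvivalFit(
        family="royston_parmar",
        params={f"gamma{j}": float(g) for j, g in enumerate(vec[:n_gamma])},
        beta=beta,
        knots=knots,
        gammas=vec[:n_gamma].copy(),
        log_likelihood=-float(res.fun),
        n=t.size,
        n_events=n_events,
        converged=True,
        params_se=params_se,
        beta_se=beta_se,
        covariate_ranges=_covariate_ranges(records, covariates),
    )


# ---------------------------------------------------------------------------
# Predictions and annual schedules


def predict_cumulative_revision(fit: SurvivalFit, t, covariate_values=None):
    """1 - S(t | x); vectorised over t; t must be non-negative."""
    t_arr = np.asarray(t, dtype=float)
    if (np.atleast_1d(t_arr) < 0).any():
        raise ValueError("t must be non-negative")
    return fit.predict_cumulative_revision(t, covariate_values)


@dataclass
class AnnualRevisionSchedule:
    """Conditional revision probability per annual cycle.

    ``probs[t-1]`` is p_t = (S(t-1) - S(t)) / S(t-1); the running product of
    (1 - p_t) reproduces S(t).
    """

    probs: np.ndarray

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if ((self.probs < 0) | (self.probs > 1)).any():
            raise ValueError("annual probabilities must lie in [0, 1]")

    def __len__(self) -> int:
        return self.probs.size

    def survival(self, horizon: Optional[int] = None) -> float:
        h = self.probs.size if horizon is None else horizon
        return float(np.prod(1.0 - self.probs[:h]))

    @classmethod
    def constant(cls, p: float, horizon: int) -> "AnnualRevisionSchedule":
        return cls(np.full(horizon, p))

    @classmethod
    def zero(cls, horizon: int) -> "AnnualRevisionSchedule":
        return cls(np.zeros(horizon))


def annual_transition_probs(
    fit: SurvivalFit, covariate_values=None, horizon: int = 10
) -> AnnualRevisionSchedule:
    """Annual conditional revision probabilities out to ``horizon`` years."""
    if horizon < 1 or int(horizon) != horizon:
        raise ValueError("horizon must be a positive integer")
    grid = np.arange(int(horizon) + 1, dtype=float)
    S = np.atleast_1d(fit.predict_survival(grid, covariate_values))
    probs = []
    for i in range(1, S.size):
        if S[i - 1] <= 0.0:
            warnings.warn(
                f"survival reached 0 at cycle {i - 1}; schedule truncated",
                stacklevel=2,
            )
            break
        probs.append((S[i - 1] - S[i]) / S[i - 1])
    return AnnualRevisionSchedule(np.clip(np.asarray(probs), 0.0, 1.0))
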