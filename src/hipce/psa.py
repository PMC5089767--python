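"""Probabilistic sensitivity analysis.

Uncertain inputs carry Beta (probabilities, utilities) or Gamma (costs)
distributions.  Each iteration draws every uncertain parameter once — the
same draw feeds both strategy arms wherever a parameter is shared — reruns
the cohort model for both arms, and records the incremental cost and QALY
pair.  Summaries include the ICER of means and the cost-effectiveness
acceptability curve (fraction of iterations with positive net monetary
benefit at each willingness-to-pay value).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .markov import ModelInputs, run_cohort

__all__ = [
    "DistributionSpec",
    "PSAResult",
    "beta_mean",
    "beta_from_moments",
    "gamma_from_moments",
    "run_psa",
    "ceac",
    "default_wtp_grid",
]

_MOMENT_CAP = 1e9  # reject Beta fits with absurd concentration


def beta_mean(alpha: float, beta: float) -> float:
    """Mean alpha / (alpha + beta) of a Beta distribution."""
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    return alpha / (alpha + beta)


def beta_from_moments(mean: float, se: float) -> Tuple[float, float]:
    """Method-of-moments Beta parameters from a mean and standard error."""
    if not 0.0 < mean < 1.0:
        raise ValueError("mean must lie strictly in (0, 1)")
    var = se * se
    bound = mean * (1.0 - mean)
    if not 0.0 < var < bound:
        raise ValueError(
            f"se^2 must lie in (0, mean*(1-mean)) = (0, {bound:.6g}) for a Beta"
        )
    nu = bound / var - 1.0
    alpha = mean * nu
    beta = (1.0 - mean) * nu
    if alpha > _MOMENT_CAP or beta > _MOMENT_CAP:
        raise ValueError(
            f"se too small: implied Beta parameters exceed cap {_MOMENT_CAP:g}"
        )
    return alpha, beta


def gamma_from_moments(mean: float, se: float) -> Tuple[float, float]:
    """Method-of-moments Gamma (shape, scale) from a mean and standard error."""
    if mean <= 0 or se <= 0:
        raise ValueError("mean and se must be positive")
    shape = (mean / se) ** 2
    scale = se * se / mean
    return shape, scale


@dataclass(frozen=True)
class DistributionSpec:
    """One uncertain model input: beta, gamma, or a fixed value."""

    kind: str
    params: Mapping[str, float]
    source_mean: Optional[float] = None
    source_se: Optional[float] = None

    def __post_init__(self):
        if self.kind not in ("beta", "gamma", "fixed"):
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if self.kind == "beta":
            if self.params["alpha"] <= 0 or self.params["beta"] <= 0:
                raise ValueError("beta parameters must be positive")
        elif self.kind == "gamma":
            if self.params["shape"] <= 0 or self.params["scale"] <= 0:
                raise ValueError("gamma parameters must be positive")

    @classmethod
    def beta(cls, alpha: float, beta: float, **kw) -> "DistributionSpec":
        return cls("beta", {"alpha": alpha, "beta": beta}, **kw)

    @classmethod
    def gamma(cls, shape: float, scale: float, **kw) -> "DistributionSpec":
        return cls("gamma", {"shape": shape, "scale": scale}, **kw)

    @classmethod
    def fixed(cls, value: float, **kw) -> "DistributionSpec":
        return cls("fixed", {"value": value}, **kw)

    @classmethod
    def beta_moments(cls, mean: float, se: float) -> "DistributionSpec":
        a, b = beta_from_moments(mean, se)
        return cls.beta(a, b, source_mean=mean, source_se=se)

    @classmethod
    def gamma_moments(cls, mean: float, se: float) -> "DistributionSpec":
        shape, scale = gamma_from_moments(mean, se)
        return cls.gamma(shape, scale, source_mean=mean, source_se=se)

    def mean(self) -> float:
        if self.kind == "beta":
            return beta_mean(self.params["alpha"], self.params["beta"])
        if self.kind == "gamma":
            return self.params["shape"] * self.params["scale"]
        return self.params["value"]

    def rvs(self, rng: np.random.Generator, size=None):
        if self.kind == "beta":
            return rng.beta(self.params["alpha"], self.params["beta"], size=size)
        if self.kind == "gamma":
            return rng.gamma(self.params["shape"], self.params["scale"], size=size)
        return self.params["value"] if size is None else np.full(size, self.params["value"])


def default_wtp_grid() -> np.ndarray:
    """£0-£50,000 in £500 steps (includes the £20,000 threshold)."""
    return np.arange(0.0, 50_000.0 + 1.0, 500.0)


@dataclass
class PSAResult:
    """Per-iteration incremental outcomes plus seeded provenance."""

    iterations: pd.DataFrame  # columns: iteration, d_cost, d_qaly
    n_iterations: int
    seed: Optional[int]
    wtp_grid: np.ndarray = field(default_factory=default_wtp_grid)
    n_aborted: int = 0

    @property
    def mean_delta_cost(self) -> float:
        return float(self.iterations["d_cost"].mean())

    @property
    def mean_delta_qalys(self) -> float:
        return float(self.iterations["d_qaly"].mean())

    def icer_of_means(self) -> Optional[float]:
        dq = self.mean_delta_qalys
        if dq == 0.0:
            return None
        return self.mean_delta_cost / dq

    def prob_cost_effective(self, wtp: float) -> float:
        nmb = wtp * self.iterations["d_qaly"] - self.iterations["d_cost"]
        return float((nmb > 0).mean())

    def ceac(self, wtp_grid=None) -> pd.DataFrame:
        return ceac(self, wtp_grid if wtp_grid is not None else self.wtp_grid)

    def to_csv(self, path) -> None:
        self.iterations.to_csv(path, index=False)


def run_psa(
    distributions: Dict[str, DistributionSpec],
    build_inputs: Callable[[Dict[str, float]], Tuple[ModelInputs, ModelInputs]],
    start_age: int,
    sex: str,
    horizon,
    n: int = 1000,
    seed: Optional[int] = None,
    wtp_grid=None,
) -> PSAResult:
    """Sample, rerun the cohort model per draw, and collect (dC, dQ) pairs.

    ``build_inputs`` receives one draw per named distribution and must
    return the two strategy arms built from that single draw set — shared
    parameters therefore use the same value in both arms by construction.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    names = list(distributions.keys())
    rows = []
    n_aborted = 0
    for it in range(n):
        draws = {name: float(distributions[name].rvs(rng)) for name in names}
        try:
            inputs_a, inputs_b = build_inputs(draws)
            res_a = run_cohort(inputs_a, start_age, sex, horizon, strategy="A")
            res_b = run_cohort(inputs_b, start_age, sex, horizon, strategy="B")
        except ValueError:
            n_aborted += 1
            continue
        rows.append(
            (it, res_a.total_cost - res_b.total_cost, res_a.total_qalys - res_b.total_qalys)
        )
    frame = pd.DataFrame(rows, columns=["iteration", "d_cost", "d_qaly"])
    grid = np.asarray(wtp_grid, dtype=float) if wtp_grid is not None else default_wtp_grid()
    return PSAResult(
        iterations=frame,
        n_iterations=len(rows),
        seed=seed,
        wtp_grid=grid,
        n_aborted=n_aborted,
    )


def ceac(psa: PSAResult, wtp_grid: Sequence[float]) -> pd.DataFrame:
    """Fraction of iterations with wtp * dQ - dC > 0, per grid point.

    Ties (net monetary benefit exactly zero) count as not cost-effective.
    """
    grid = np.asarray(wtp_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("wtp_grid must be non-empty")
    if psa.iterations.empty:
        raise ValueError("PSA has no successful iterations")
    dq = psa.iterations["d_qaly"].to_numpy()
    dc = psa.iterations["d_cost"].to_numpy()
    probs = [(lam * dq - dc > 0).mean() for lam in grid]
    return pd.DataFrame({"wtp": grid, "probability": probs})
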