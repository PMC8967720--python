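"""Probabilistic and deterministic sensitivity analysis.

PSA samples parameter distributions, re-evaluates the decision model per
draw, and summarises the (delta_cost, delta_qaly) cloud with percentile
credible intervals and a CEAC.  One-way analysis re-evaluates the
deterministic model at each parameter's bounds and sorts by swing
(tornado ordering).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cea import CEACCurve, DEFAULT_LAMBDA_GRID, ceac

FAMILIES = ("beta", "gamma", "normal", "lognormal", "dirichlet", "fixed")


class InvalidDraw(Exception):
    """Raised by an evaluator when a sampled parameter set yields an
    invalid model (e.g. a non-stochastic transition matrix)."""


@dataclass(frozen=True)
class ParameterDistribution:
    """Sampling distribution for one model parameter.

    Conventional families: beta for utilities (support bounded above by
    1), gamma / lognormal for costs (non-negative), dirichlet for
    probability vectors, normal for unbounded effects, fixed for
    point-mass parameters.
    """

    name: str
    family: str
    params: Mapping[str, float | Sequence[float]]
    low: float | None = None
    high: float | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")

    def sample(self, rng: np.random.Generator):
        p = self.params
        if self.family == "fixed":
            return p["value"]
        if self.family == "beta":
            draw = rng.beta(p["a"], p["b"])
        elif self.family == "gamma":
            draw = rng.gamma(p["shape"], p["scale"])
        elif self.family == "normal":
            draw = rng.normal(p["mu"], p["sd"])
        elif self.family == "lognormal":
            draw = rng.lognormal(p["mu"], p["sd"])
        else:  # dirichlet
            return rng.dirichlet(np.asarray(p["alpha"], dtype=float))
        # enforce bounds by resampling (cheap; distributions are scalar)
        tries = 0
        while (self.low is not None and draw < self.low) or (
            self.high is not None and draw > self.high
        ):
            tries += 1
            if tries > 1000:
                raise ValueError(f"cannot satisfy bounds for {self.name}")
            draw = self.sample_unbounded(rng)
        return float(draw)

    def sample_unbounded(self, rng: np.random.Generator) -> float:
        p = self.params
        if self.family == "beta":
            return rng.beta(p["a"], p["b"])
        if self.family == "gamma":
            return rng.gamma(p["shape"], p["scale"])
        if self.family == "normal":
            return rng.normal(p["mu"], p["sd"])
        if self.family == "lognormal":
            return rng.lognormal(p["mu"], p["sd"])
        raise ValueError(self.family)


def sample_parameters(
    distributions: Sequence[ParameterDistribution],
    n: int,
    seed: int | None = None,
) -> list[dict]:
    """Draw ``n`` parameter sets; reproducible given the seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return [{d.name: d.sample(rng) for d in distributions} for _ in range(n)]


@dataclass
class PSAResult:
    draws: np.ndarray  # (n_accepted, 2): delta_cost, delta_qaly
    mean_delta_cost: float
    mean_delta_qaly: float
    ci_cost: tuple[float, float]
    ci_qaly: tuple[float, float]
    ceac: CEACCurve
    n_rejected: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.draws, columns=["delta_cost", "delta_qaly"])


def psa_run(
    evaluate: Callable[[dict], tuple[float, float]],
    distributions: Sequence[ParameterDistribution],
    n: int,
    seed: int | None = None,
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
) -> PSAResult:
    """Probabilistic sensitivity analysis.

    ``evaluate`` maps one sampled parameter dict to (delta_cost,
    delta_qaly); draws for which it raises :class:`InvalidDraw` are
    rejected and counted rather than clamped.
    """
    parameter_sets = sample_parameters(distributions, n, seed)
    accepted: list[tuple[float, float]] = []
    rejected = 0
    for params in parameter_sets:
        try:
            dc, dq = evaluate(params)
        except InvalidDraw:
            rejected += 1
            continue
        if not (np.isfinite(dc) and np.isfinite(dq)):
            rejected += 1
            continue
        accepted.append((float(dc), float(dq)))
    if not accepted:
        raise ValueError("every PSA draw was rejected")
    draws = np.array(accepted)
    ci_cost = tuple(np.percentile(draws[:, 0], [2.5, 97.5]))
    ci_qaly = tuple(np.percentile(draws[:, 1], [2.5, 97.5]))
    return PSAResult(
        draws=draws,
        mean_delta_cost=float(draws[:, 0].mean()),
        mean_delta_qaly=float(draws[:, 1].mean()),
        ci_cost=ci_cost,
        ci_qaly=ci_qaly,
        ceac=ceac(draws, lambda_grid),
        n_rejected=rejected,
    )


def one_way(
    evaluate: Callable[[dict], tuple[float, float]],
    base_params: Mapping[str, float],
    ranges: Mapping[str, tuple[float, float]],
    outcome: str = "delta_cost",
) -> pd.DataFrame:
    """Deterministic one-way sensitivity analysis (tornado table).

    Each parameter is evaluated at its low and high bound with every
    other parameter at base value; rows are sorted by absolute swing.
    Bounds must bracket the base value.
    """
    which = {"delta_cost": 0, "delta_qaly": 1}[outcome]
    base_value = evaluate(dict(base_params))[which]
    rows = []
    for name, (low, high) in ranges.items():
        if name not in base_params:
            raise KeyError(f"unknown parameter {name!r}")
        base = base_params[name]
        if not (low <= base <= high):
            raise ValueError(
                f"range ({low}, {high}) for {name!r} does not bracket base {base}"
            )
        at_low = evaluate({**base_params, name: low})[which]
        at_high = evaluate({**base_params, name: high})[which]
        rows.append(
            {
                "parameter": name,
                "low": low,
                "high": high,
                "result_low": at_low,
                "result_high": at_high,
                "swing": abs(at_high - at_low),
            }
        )
    frame = pd.DataFrame(rows).sort_values("swing", ascending=False, kind="stable")
    frame.attrs["base_result"] = base_value
    return frame.reset_index(drop=True)
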