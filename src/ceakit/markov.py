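"""Lifetime Markov cohort extrapolation over SPPB states.

Fourteen states: SPPB scores 0-12 plus an absorbing dead state; annual
cycles.  SPPB transitions among the living come from a
proportional-odds ordinal model fitted to control-arm panel data;
mortality comes from a life table and is identical in every living
state (no mortality effect), so all QALY differences arise from utility
weights.  Model time starts at trial month 24, two years after
randomisation, and discounting is anchored at randomisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .cea import CEEstimate, classify_icer

N_SPPB = 13  # states 0..12
DEAD = N_SPPB
N_STATES = N_SPPB + 1

AGE_GRID = tuple(range(65, 96, 5))


@dataclass
class LifeTable:
    """Annual death probabilities q(age, sex)."""

    table: pd.DataFrame  # columns: age, female, qx

    def __post_init__(self) -> None:
        required = {"age", "female", "qx"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"life table needs columns {sorted(required)}")
        if ((self.table["qx"] <= 0) | (self.table["qx"] >= 1)).any():
            raise ValueError("life-table qx must lie in (0, 1)")
        self._lookup = {
            (int(row.age), int(row.female)): float(row.qx)
            for row in self.table.itertuples()
        }

    def q(self, age: int, female: int) -> float:
        key = (int(age), int(female))
        if key not in self._lookup:
            raise KeyError(f"life table does not cover age={age}, female={female}")
        return self._lookup[key]

    @property
    def max_age(self) -> int:
        return int(self.table["age"].max())

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        return cls(pd.read_csv(path, comment="#"))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


class OrdinalTransitionModel:
    """Proportional-odds model for next-year SPPB given current SPPB, age, sex."""

    degenerate = False

    def __init__(self, result, categories: np.ndarray):
        self._result = result
        self.categories = np.asarray(categories, dtype=int)

    def predict_probs(self, current_sppb: int, age: float, female: int) -> np.ndarray:
        """Probability vector over SPPB 0..12 for the next cycle."""
        exog = np.array([[float(current_sppb), float(age), float(female)]])
        probs = np.asarray(self._result.model.predict(self._result.params, exog))[0]
        out = np.zeros(N_SPPB)
        out[self.categories] = probs
        # numerical cleanup; ordinal probabilities already sum to 1
        out = np.clip(out, 0.0, None)
        return out / out.sum()

    @property
    def params(self) -> np.ndarray:
        return np.asarray(self._result.params)

    @property
    def bse(self) -> np.ndarray:
        return np.asarray(self._result.bse)


class ConstantTransitionModel:
    """Degenerate model: every living state moves to one fixed SPPB score."""

    degenerate = True

    def __init__(self, state: int):
        self.state = int(state)

    def predict_probs(self, current_sppb: int, age: float, female: int) -> np.ndarray:
        out = np.zeros(N_SPPB)
        out[self.state] = 1.0
        return out


class IdentityTransitionModel:
    """Perfect persistence: SPPB never changes (flagged degenerate)."""

    degenerate = True

    def predict_probs(self, current_sppb: int, age: float, female: int) -> np.ndarray:
        out = np.zeros(N_SPPB)
        out[int(current_sppb)] = 1.0
        return out


def fit_transition_model(panel: pd.DataFrame):
    """Fit the annual SPPB transition model to control-arm panel data.

    ``panel`` columns: sppb (current), sppb_next, age, female.  Returns
    an :class:`OrdinalTransitionModel`, or a flagged degenerate model
    when the outcome carries no information (a single observed next
    state, or perfect persistence).
    """
    for col in ("sppb", "sppb_next", "age", "female"):
        if col not in panel.columns:
            raise KeyError(f"panel missing column {col!r}")
    sppb = panel["sppb"].to_numpy()
    sppb_next = panel["sppb_next"].to_numpy()
    for arr in (sppb, sppb_next):
        if ((arr < 0) | (arr > 12)).any():
            raise ValueError("SPPB scores must lie in 0..12")
    uniq = np.unique(sppb_next)
    if uniq.size == 1:
        return ConstantTransitionModel(int(uniq[0]))
    if (sppb_next == sppb).all():
        return IdentityTransitionModel()

    endog = pd.Categorical(sppb_next, categories=sorted(uniq), ordered=True)
    exog = panel[["sppb", "age", "female"]].astype(float)
    model = OrderedModel(endog, exog, distr="logit")
    result = model.fit(method="lbfgs", maxiter=500, disp=0)
    return OrdinalTransitionModel(result, categories=np.array(sorted(uniq)))


def build_transition_matrix(
    model, age: float, female: int, life_table: LifeTable
) -> np.ndarray:
    """Assemble the 14x14 annual transition matrix at one age.

    Each living row sends q(age, sex) to dead and spreads the remaining
    (1 - q) over SPPB states by the ordinal model; mortality is
    independent of SPPB.  The dead row is absorbing.
    """
    q = life_table.q(int(age), female)
    if not 0 <= q <= 1:
        raise ValueError(f"death probability {q} outside [0, 1]")
    P = np.zeros((N_STATES, N_STATES))
    for s in range(N_SPPB):
        probs = model.predict_probs(s, age, female)
        P[s, :N_SPPB] = (1.0 - q) * probs
        P[s, DEAD] = q
    P[DEAD, DEAD] = 1.0
    return P


@dataclass
class StateValues:
    """Annual cost and utility attached to each SPPB state."""

    annual_cost: np.ndarray
    utility: np.ndarray

    def __post_init__(self) -> None:
        self.annual_cost = np.asarray(self.annual_cost, dtype=float)
        self.utility = np.asarray(self.utility, dtype=float)
        if self.annual_cost.shape != (N_SPPB,) or self.utility.shape != (N_SPPB,):
            raise ValueError(f"state values must have length {N_SPPB}")
        if (self.utility > 1.0 + 1e-12).any():
            raise ValueError("state utilities must be <= 1")


def fit_state_values(data: pd.DataFrame) -> StateValues:
    """Regress annual cost and utility on SPPB (control data only).

    Linear in SPPB by default, evaluated at each of the 13 states, so
    states unobserved in the data are covered by model-based smoothing.
    Fitted utilities are capped at 1.
    """
    if len(data) == 0:
        raise ValueError("no data to fit state values")
    for col in ("sppb", "annual_cost", "utility"):
        if col not in data.columns:
            raise KeyError(f"state-value data missing column {col!r}")
    s = data["sppb"].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(s), s])
    grid = np.column_stack([np.ones(N_SPPB), np.arange(N_SPPB, dtype=float)])
    beta_cost, *_ = np.linalg.lstsq(X, data["annual_cost"].to_numpy(float), rcond=None)
    beta_util, *_ = np.linalg.lstsq(X, data["utility"].to_numpy(float), rcond=None)
    return StateValues(
        annual_cost=grid @ beta_cost,
        utility=np.minimum(grid @ beta_util, 1.0),
    )


@dataclass
class MarkovSpec:
    """Configuration of one cohort run."""

    start_age: int
    female: int
    start_distribution: np.ndarray  # over SPPB 0..12 (+ optional dead entry)
    discount_rate: float = 0.035
    horizon: int | None = None  # cycles; default runs to age 100
    time_offset_years: float = 2.0  # model starts at trial month 24
    half_cycle_correction: bool = False
    max_age: int = 100

    def __post_init__(self) -> None:
        dist = np.asarray(self.start_distribution, dtype=float)
        if dist.shape == (N_SPPB,):
            dist = np.concatenate([dist, [0.0]])
        if dist.shape != (N_STATES,):
            raise ValueError(f"start distribution must have {N_SPPB} or {N_STATES} entries")
        if abs(dist.sum() - 1.0) > 1e-9:
            raise ValueError("start distribution must sum to 1")
        if (dist < 0).any():
            raise ValueError("start distribution must be non-negative")
        self.start_distribution = dist
        if self.horizon is None:
            self.horizon = max(self.max_age - self.start_age, 0)
        if self.horizon < 0:
            raise ValueError("horizon must be >= 0")


@dataclass
class CohortTrace:
    """Occupancy over time plus discounted and undiscounted accumulators."""

    occupancy: np.ndarray  # (horizon + 1, 14)
    discounted_cost: float
    discounted_qaly: float
    undiscounted_cost: float
    undiscounted_qaly: float
    life_years_by_band: dict[str, float]
    life_expectancy: float


def run_cohort(
    spec: MarkovSpec,
    transition_for_age: Callable[[float], np.ndarray],
    values: StateValues,
) -> CohortTrace:
    """Propagate the cohort and accumulate discounted costs and QALYs.

    Cycle t (one year starting at age ``start_age + t``) accrues
    occupancy x state values, discounted by (1+r)^-(t + offset) so that
    the model phase shares the randomisation time axis with the trial
    phase.  With the half-cycle correction enabled, accrual uses the
    mean of start- and end-of-cycle occupancy.
    """
    H = spec.horizon
    occ = np.zeros((H + 1, N_STATES))
    occ[0] = spec.start_distribution
    for t in range(H):
        P = transition_for_age(spec.start_age + t)
        occ[t + 1] = occ[t] @ P

    r = spec.discount_rate
    disc = (1.0 + r) ** -(np.arange(H) + spec.time_offset_years)
    if spec.half_cycle_correction:
        living = 0.5 * (occ[:-1, :N_SPPB] + occ[1:, :N_SPPB])
    else:
        living = occ[:-1, :N_SPPB]
    cost_per_cycle = living @ values.annual_cost
    qaly_per_cycle = living @ values.utility
    alive_per_cycle = living.sum(axis=1)
    band_hi = living[:, 8:].sum()  # SPPB 8-12
    band_lo = living[:, :8].sum()  # SPPB 0-7

    return CohortTrace(
        occupancy=occ,
        discounted_cost=float(disc @ cost_per_cycle),
        discounted_qaly=float(disc @ qaly_per_cycle),
        undiscounted_cost=float(cost_per_cycle.sum()),
        undiscounted_qaly=float(qaly_per_cycle.sum()),
        life_years_by_band={"sppb_8_12": float(band_hi), "sppb_0_7": float(band_lo)},
        life_expectancy=float(alive_per_cycle.sum()),
    )


def transition_provider(
    model, female: int, life_table: LifeTable
) -> Callable[[float], np.ndarray]:
    """Age -> 14x14 matrix closure with simple memoisation.

    Ages beyond the life table cap transition everyone to dead."""
    cache: dict[int, np.ndarray] = {}

    def provider(age: float) -> np.ndarray:
        a = int(age)
        if a not in cache:
            if a > life_table.max_age:
                P = np.zeros((N_STATES, N_STATES))
                P[:, DEAD] = 1.0
                cache[a] = P
            else:
                cache[a] = build_transition_matrix(model, a, female, life_table)
        return cache[a]

    return provider


def lifetime_cea(
    trial_delta_cost: float,
    trial_delta_qaly: float,
    start_intervention: np.ndarray,
    start_control: np.ndarray,
    spec: MarkovSpec,
    model,
    values: StateValues,
    life_table: LifeTable,
    icer_rounding: float | None = 50.0,
) -> CEEstimate:
    """Trial-phase deltas plus discounted post-24-month model deltas.

    The two arms share every model input except the starting SPPB
    distribution, so mortality (hence life expectancy) is identical by
    construction.
    """
    provider = transition_provider(model, spec.female, life_table)
    traces = {}
    for name, start in (("int", start_intervention), ("ctl", start_control)):
        arm_spec = MarkovSpec(
            start_age=spec.start_age,
            female=spec.female,
            start_distribution=np.asarray(start, dtype=float),
            discount_rate=spec.discount_rate,
            horizon=spec.horizon,
            time_offset_years=spec.time_offset_years,
            half_cycle_correction=spec.half_cycle_correction,
            max_age=spec.max_age,
        )
        traces[name] = run_cohort(arm_spec, provider, values)
    delta_cost = trial_delta_cost + traces["int"].discounted_cost - traces["ctl"].discounted_cost
    delta_qaly = trial_delta_qaly + traces["int"].discounted_qaly - traces["ctl"].discounted_qaly
    return CEEstimate(
        delta_cost=delta_cost,
        delta_qaly=delta_qaly,
        icer=classify_icer(delta_cost, delta_qaly, rounding=icer_rounding),
    )


def start_distribution_from_sppb(scores: Sequence[int]) -> np.ndarray:
    """Empirical histogram of 24-month SPPB scores as a start distribution."""
    scores = np.asarray(scores, dtype=int)
    if scores.size == 0:
        raise ValueError("no SPPB scores supplied")
    if ((scores < 0) | (scores > 12)).any():
        raise ValueError("SPPB scores must lie in 0..12")
    hist = np.bincount(scores, minlength=N_SPPB).astype(float)
    return hist / hist.sum()


def population_weighted(
    results: Sequence[CEEstimate], weights: Sequence[float]
) -> CEEstimate:
    """Weighted mean of per-profile incremental results."""
    w = np.asarray(weights, dtype=float)
    if len(results) != w.size:
        raise ValueError("results and weights lengths differ")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    dc = float(sum(wi * r.delta_cost for wi, r in zip(w, results)))
    dq = float(sum(wi * r.delta_qaly for wi, r in zip(w, results)))
    return CEEstimate(delta_cost=dc, delta_qaly=dq, icer=classify_icer(dc, dq))


def snap_to_age_grid(age: float, grid: Sequence[int] = AGE_GRID) -> int:
    """Nearest modelled age profile (e.g. mean age 77 -> the 75 profile)."""
    grid = np.asarray(grid)
    return int(grid[np.argmin(np.abs(grid - age))])
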