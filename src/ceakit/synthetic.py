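"""Synthetic trial data with known ground truth.

Generates participant-level datasets shaped like a two-arm pragmatic
trial in older adults (SPPB 4-9 at entry, 1:1 allocation, questionnaire
follow-up at 6/12/24 months), together with toy value-set tables and a
toy life table, so that every pipeline stage can be exercised and its
estimates checked against the generator's configured true effects.

Calibration notes
-----------------
* The treatment effect on utility is applied on the latent scale at each
  follow-up timepoint so that the expected incremental QALY equals the
  configured value under the package's own AUC weights.  Part of the
  utility effect flows through the SPPB trajectory (utilities are
  SPPB-linked); the residual is applied directly, so the total is exact.
* Resource-use counts are negative binomial with means linear in latent
  SPPB.  The SPPB-mediated cost effect is computed in closed form and
  the remainder of the configured incremental cost (net of the
  intervention delivery cost) is applied as an additive shift to the
  overnight-stay count mean, so the expected discounted incremental
  total cost equals the configured value.
* Complete cases are selected by Gumbel-perturbed ranking of a
  missingness score that depends only on observed quantities (arm,
  attendance, baseline utility), giving an exact complete-case count
  and an MAR mechanism.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .resources import UnitCostTable
from .valuation import INSTRUMENTS, ValueSetTable, qaly_weights

#: value-set kinds -> (profile system, worst-profile utility floor)
VALUE_SET_KINDS = {
    "crosswalk": ("EQ5D5L", -0.594),
    "EQ5D5L": ("EQ5D5L", -0.285),
    "SF6D": ("SF6D", 0.203),
}

#: resource items: unit cost (GBP), base 6-month count mean, decline per SPPB point
RESOURCE_ITEMS: dict[str, tuple[float, float, float]] = {
    "gp_visit": (39.0, 3.0, 0.12),
    "nurse_visit": (11.0, 2.5, 0.10),
    "outpatient": (135.0, 1.2, 0.06),
    "emergency": (160.0, 0.35, 0.02),
    "overnight_stay": (345.0, 1.9, 0.09),
    "social_care": (25.0, 2.0, 0.15),
}

#: the item whose mean absorbs the direct (non-SPPB-mediated) cost effect
CALIBRATION_ITEM = "overnight_stay"

PERIOD_SUFFIXES = ("base", "0_6", "6_12", "18_24")

_SPPB_EFFECT_FRACTIONS = {6: 0.6, 12: 0.9, 24: 1.0}
_CONTROL_SPPB_DRIFT = {6: -0.3, 12: -0.5, 24: -0.9}
_CONTROL_UTILITY_DRIFT = {6: -0.01, 12: -0.015, 24: -0.03}
_UTILITY_PER_SPPB = 0.015
_NB_DISPERSION = 1.5


def default_unit_cost_table() -> UnitCostTable:
    return UnitCostTable(
        prices={item: cost for item, (cost, _, _) in RESOURCE_ITEMS.items()}
    )


@dataclass
class SynthConfig:
    """Generator configuration; defaults emulate the reference trial."""

    n: int = 777
    prop_female: float = 0.66
    age_mean: float = 77.0
    age_sd: float = 6.0
    age_min: float = 65.0
    age_max: float = 97.0
    sites: int = 3
    true_sppb_24m: float = 0.49
    true_incremental_qaly: float = 0.040
    true_incremental_cost: float = -103.0
    intervention_cost_pp: float = 622.0
    complete_case_fraction: float = 0.58
    discount_rate: float = 0.035
    value_set_kind: str = "crosswalk"
    baseline_cost_imbalance: float = 0.0  # optional knob, off by default

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if not 0 < self.complete_case_fraction <= 1:
            raise ValueError("complete-case fraction must lie in (0, 1]")
        if not 0 <= self.prop_female <= 1:
            raise ValueError("prop_female must lie in [0, 1]")
        if self.value_set_kind not in VALUE_SET_KINDS:
            raise ValueError(f"unknown value set kind {self.value_set_kind!r}")
        w = qaly_weights(self.discount_rate)
        per_timepoint = self.true_incremental_qaly / float(w[1:].sum())
        if abs(per_timepoint) > 0.2:
            raise ValueError(
                f"incremental QALY {self.true_incremental_qaly} implies a "
                f"per-timepoint utility shift of {per_timepoint:.3f}, outside "
                "the plausible utility range"
            )


@dataclass
class GroundTruth:
    """The generator's true parameters, serialised alongside each dataset."""

    incremental_qaly: float
    incremental_cost: float
    sppb_effect_24m: float
    utility_shift_per_timepoint: float
    cost_shift_per_period: float
    intervention_cost_pp: float
    discount_rate: float
    value_set_kind: str
    n: int
    seed: int | None

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def generate_value_set(kind: str, seed: int | None = None) -> ValueSetTable:
    """A toy value set covering every profile of the instrument.

    Monotone non-increasing in each dimension's level, full health maps
    to 1.0 and the worst profile to the instrument's published floor.
    The per-level decrements are drawn from the seed and renormalised,
    so different seeds give different (still monotone) tables.
    """
    if kind not in VALUE_SET_KINDS:
        raise ValueError(f"unknown value set kind {kind!r}")
    system, floor = VALUE_SET_KINDS[kind]
    level_counts = INSTRUMENTS[system]
    rng = np.random.default_rng(seed)
    # cumulative decrement per dimension/level, scaled so the worst
    # profile lands exactly on the floor
    decrements = []
    for hi in level_counts:
        steps = rng.uniform(0.5, 1.5, size=hi - 1)
        decrements.append(np.concatenate([[0.0], np.cumsum(steps)]))
    total_worst = sum(d[-1] for d in decrements)
    scale = (1.0 - floor) / total_worst
    decrements = [d * scale for d in decrements]
    mapping = {}
    for levels in itertools.product(*(range(1, hi + 1) for hi in level_counts)):
        u = 1.0 - sum(decrements[d][lv - 1] for d, lv in enumerate(levels))
        mapping[levels] = float(u)
    worst = tuple(level_counts)
    mapping[worst] = floor  # exact, not float-accumulated
    return ValueSetTable(instrument=system, mapping=mapping, floor=floor)


def generate_life_table() -> "pd.DataFrame":
    """Toy Gompertz life table, ages 60-105 by sex.

    Death probability strictly increasing in age, female below male at
    every age, everything inside (0, 1).  Returned as a plain frame
    compatible with :class:`ceakit.markov.LifeTable`.
    """
    ages = np.arange(60, 106)
    rows = []
    for female, a in ((1, 2.0e-5), (0, 3.2e-5)):
        hazard = a * np.exp(0.1 * ages)
        qx = hazard / (1.0 + hazard)  # logistic keeps qx strictly in (0, 1)
        for age, q in zip(ages, qx):
            rows.append({"age": int(age), "female": female, "qx": float(q)})
    return pd.DataFrame(rows)


class _ProfileSnapper:
    """Maps a latent utility to the nearest profile of a value set."""

    def __init__(self, value_set: ValueSetTable):
        items = sorted(value_set.mapping.items(), key=lambda kv: kv[1])
        self.utils = np.array([u for _, u in items])
        self.keys = np.array(["-".join(map(str, lv)) for lv, _ in items])

    def snap(self, latent: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        idx = np.searchsorted(self.utils, latent)
        idx = np.clip(idx, 1, len(self.utils) - 1)
        lower = idx - 1
        use_lower = np.abs(latent - self.utils[lower]) <= np.abs(
            latent - self.utils[idx]
        )
        chosen = np.where(use_lower, lower, idx)
        return self.keys[chosen], self.utils[chosen]


def _period_weights(r: float) -> dict[str, float]:
    """Contribution of each observed period's cost to the discounted
    24-month total, given the gap-period (12-18 m) neighbour-mean rule."""
    d = 1.0 / (1.0 + r)
    return {"0_6": 1.0, "6_12": 1.0 + 0.5 * d, "18_24": 1.5 * d}


def generate_trial(
    config: SynthConfig | None = None,
    seed: int | None = 1,
    value_set: ValueSetTable | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate one participant-level trial dataset plus its ground truth.

    Columns: identifiers and covariates (arm, age, female, site,
    attendance), SPPB at 0/6/12/24 months (always observed), EQ-5D
    profile keys at 0/6/12/24 months, and per-item resource counts for
    the baseline recall and the 0-6 / 6-12 / 18-24-month periods.
    Questionnaire blocks are missing for the configured fraction of
    participants (MAR in arm, attendance and baseline utility).
    """
    config = config or SynthConfig()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = config.n
    if value_set is None:
        value_set = generate_value_set(config.value_set_kind, seed=12345)
    snapper = _ProfileSnapper(value_set)

    # --- covariates -----------------------------------------------------
    arm = rng.permutation(np.arange(n) % 2)
    female = (rng.random(n) < config.prop_female).astype(int)
    age = np.clip(
        rng.normal(config.age_mean, config.age_sd, size=n),
        config.age_min,
        config.age_max,
    )
    site = rng.integers(0, config.sites, size=n)
    attendance = np.where(arm == 1, rng.beta(2.0, 1.1, size=n), 0.0)

    # --- SPPB trajectories ----------------------------------------------
    sppb0 = rng.choice(
        np.arange(4, 10), size=n, p=[0.12, 0.18, 0.20, 0.20, 0.18, 0.12]
    )
    latent_sppb = {0: sppb0.astype(float)}
    for t in (6, 12, 24):
        eff = config.true_sppb_24m * _SPPB_EFFECT_FRACTIONS[t]
        latent_sppb[t] = (
            sppb0
            + _CONTROL_SPPB_DRIFT[t]
            + arm * eff
            + rng.normal(0.0, 1.1, size=n)
        )
    observed_sppb = {
        t: np.clip(np.round(latent_sppb[t]), 0, 12).astype(int)
        for t in (0, 6, 12, 24)
    }

    # --- utilities ------------------------------------------------------
    w = qaly_weights(config.discount_rate)
    delta_u = config.true_incremental_qaly / float(w[1:].sum())
    u0_lat = 0.70 + 0.018 * (sppb0 - 6.5) + rng.normal(0.0, 0.10, size=n)
    latent_u = {0: u0_lat}
    for t in (6, 12, 24):
        eff = config.true_sppb_24m * _SPPB_EFFECT_FRACTIONS[t]
        sppb_linked = _UTILITY_PER_SPPB * (latent_sppb[t] - sppb0)
        direct = delta_u - _UTILITY_PER_SPPB * eff  # residual after SPPB path
        latent_u[t] = (
            u0_lat
            + sppb_linked
            + _CONTROL_UTILITY_DRIFT[t]
            + arm * direct
            + rng.normal(0.0, 0.07, size=n)
        )
    profiles, snapped_u = {}, {}
    for t in (0, 6, 12, 24):
        profiles[t], snapped_u[t] = snapper.snap(latent_u[t])

    # --- resource-use counts --------------------------------------------
    weights = _period_weights(config.discount_rate)
    eff_by_period = {
        "0_6": config.true_sppb_24m * _SPPB_EFFECT_FRACTIONS[6],
        "6_12": config.true_sppb_24m * _SPPB_EFFECT_FRACTIONS[12],
        "18_24": config.true_sppb_24m * _SPPB_EFFECT_FRACTIONS[24],
    }
    cost_slope_total = sum(
        cost * slope for cost, _, slope in RESOURCE_ITEMS.values()
    )
    sppb_mediated = -cost_slope_total * sum(
        weights[p] * eff_by_period[p] for p in weights
    )
    target_resource_delta = config.true_incremental_cost - config.intervention_cost_pp
    residual = target_resource_delta - sppb_mediated
    cost_shift_per_period = residual / sum(weights.values())
    calib_cost = RESOURCE_ITEMS[CALIBRATION_ITEM][0]
    count_shift = cost_shift_per_period / calib_cost

    sppb_ref = {
        "base": latent_sppb[0],
        "0_6": latent_sppb[6],
        "6_12": latent_sppb[12],
        "18_24": latent_sppb[24],
    }
    counts: dict[str, np.ndarray] = {}
    for suffix, s_ref in sppb_ref.items():
        for item, (unit_cost, base, slope) in RESOURCE_ITEMS.items():
            mean = np.maximum(base - slope * s_ref, 0.02)
            if suffix != "base" and item == CALIBRATION_ITEM:
                mean = np.maximum(mean + arm * count_shift, 0.02)
            if suffix == "base" and item == CALIBRATION_ITEM:
                mean = mean + arm * config.baseline_cost_imbalance / calib_cost
            lam = rng.gamma(_NB_DISPERSION, mean / _NB_DISPERSION)
            counts[f"{item}_{suffix}"] = rng.poisson(lam).astype(float)

    # --- missingness ----------------------------------------------------
    n_complete = int(round(config.complete_case_fraction * n))
    score = (
        1.0 * arm
        - 1.8 * attendance * arm
        - 1.2 * (u0_lat - 0.70)
        + rng.gumbel(0.0, 1.0, size=n)
    )
    incomplete = np.zeros(n, dtype=bool)
    if n_complete < n:
        incomplete[np.argsort(score)[-(n - n_complete):]] = True

    frame = pd.DataFrame(
        {
            "pid": np.arange(n),
            "arm": arm,
            "age": age,
            "female": female,
            "site": site,
            "attendance": attendance,
        }
    )
    for t in (0, 6, 12, 24):
        frame[f"sppb_{t}"] = observed_sppb[t]
    for t in (0, 6, 12, 24):
        frame[f"profile_{t}"] = profiles[t]
    for col, values in counts.items():
        frame[col] = values

    # follow-up questionnaire blocks; baseline stays complete
    blocks: list[list[str]] = [["profile_6"], ["profile_12"], ["profile_24"]]
    items = list(RESOURCE_ITEMS)
    for suffix in ("0_6", "6_12", "18_24"):
        blocks.append([f"{item}_{suffix}" for item in items])
    for i in np.flatnonzero(incomplete):
        gone = rng.random(len(blocks)) < 0.5
        if not gone.any():
            gone[rng.integers(0, len(blocks))] = True
        for block, is_gone in zip(blocks, gone):
            if is_gone:
                for col in block:
                    frame.loc[i, col] = np.nan

    truth = GroundTruth(
        incremental_qaly=config.true_incremental_qaly,
        incremental_cost=config.true_incremental_cost,
        sppb_effect_24m=config.true_sppb_24m,
        utility_shift_per_timepoint=delta_u,
        cost_shift_per_period=cost_shift_per_period,
        intervention_cost_pp=config.intervention_cost_pp,
        discount_rate=config.discount_rate,
        value_set_kind=config.value_set_kind,
        n=n,
        seed=seed,
    )
    return frame, truth


def generate_ordinal_panel(
    n: int,
    beta: tuple[float, float, float] = (0.9, -0.02, 0.15),
    cutpoints: np.ndarray | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Panel drawn from a known proportional-odds transition model.

    ``beta`` holds the coefficients on (current SPPB, age, sex); the
    cutpoints default to an evenly spaced ladder over the latent scale.
    Used to check that :func:`ceakit.markov.fit_transition_model`
    recovers its generating parameters.
    """
    rng = np.random.default_rng(seed)
    if cutpoints is None:
        # 12 cutpoints for 13 categories, centred on typical x @ beta
        cutpoints = np.linspace(-4.0, 8.0, 12) + 0.9 * 6 - 0.02 * 77
    sppb = rng.integers(0, 13, size=n)
    age = rng.uniform(65, 95, size=n)
    female = rng.integers(0, 2, size=n)
    xb = beta[0] * sppb + beta[1] * age + beta[2] * female
    z = xb + rng.logistic(0.0, 1.0, size=n)
    sppb_next = (z[:, None] > cutpoints[None, :]).sum(axis=1)
    panel = pd.DataFrame(
        {"sppb": sppb, "sppb_next": sppb_next, "age": age, "female": female}
    )
    return panel, {"beta": np.asarray(beta), "cutpoints": np.asarray(cutpoints)}
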