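"""End-to-end within-trial analysis: profiles -> utilities -> costs ->
multiple imputation -> adjusted increments -> Rubin pooling."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import cea, imputation, resources, valuation
from .resources import UnitCostTable
from .synthetic import RESOURCE_ITEMS
from .valuation import ValueSetTable

UTILITY_COLS = ("u_0", "u_6", "u_12", "u_24")
COST_COLS = ("cost_base", "cost_0_6", "cost_6_12", "cost_18_24")

#: imputation-model predictors that are always observed
BASE_PREDICTORS = ("arm", "age", "female", "site", "attendance")

#: GLM covariates (stratification variables + baseline utility and cost)
DEFAULT_COVARIATES = ("age", "female", "site", "u_0", "cost_base")


def attach_utilities(frame: pd.DataFrame, value_set: ValueSetTable) -> pd.DataFrame:
    """Add u_{t} columns by value-set lookup of the profile_{t} columns."""
    out = frame.copy()
    for t in (0, 6, 12, 24):
        keys = frame[f"profile_{t}"]
        utilities = np.full(len(frame), np.nan)
        mask = keys.notna()
        for idx in np.flatnonzero(mask.to_numpy()):
            profile = valuation.HealthProfile.from_key(
                value_set.instrument, keys.iloc[idx]
            )
            utilities[idx] = valuation.lookup_utility(profile, value_set)
        out[f"u_{t}"] = utilities
    return out


def attach_period_costs(frame: pd.DataFrame, prices: UnitCostTable) -> pd.DataFrame:
    """Add per-period cost columns from the per-item count columns."""
    return resources.costs_from_counts(frame, prices, items=list(RESOURCE_ITEMS))


@dataclass
class WithinTrialResult:
    """Pooled incremental estimates and their provenance."""

    ce: cea.CEEstimate
    pooled_qaly: imputation.PooledEstimate
    pooled_cost: imputation.PooledEstimate
    per_imputation: pd.DataFrame
    m: int


def within_trial_analysis(
    frame: pd.DataFrame,
    value_set: ValueSetTable,
    prices: UnitCostTable,
    intervention_cost: float = 622.0,
    m: int = 50,
    seed: int | None = None,
    k_donors: int = 5,
    iterations: int = 10,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    discount_rate: float = 0.035,
    icer_rounding: float = 50.0,
) -> WithinTrialResult:
    """Base-case trial analysis on a raw participant table.

    Utilities and period costs are derived, missing utility / period-cost
    values are multiply imputed by PMM, each completed dataset is
    analysed with covariate-adjusted linear models, and the m arm
    contrasts are pooled by Rubin's rules.
    """
    work = attach_utilities(frame, value_set)
    work = attach_period_costs(work, prices)

    impute_vars = [c for c in UTILITY_COLS + COST_COLS if work[c].isna().any()]
    always_observed = [
        c for c in UTILITY_COLS + COST_COLS if not work[c].isna().any()
    ]
    predictors = list(BASE_PREDICTORS) + always_observed
    if impute_vars:
        completed = imputation.pmm_impute(
            work[list(BASE_PREDICTORS) + list(UTILITY_COLS) + list(COST_COLS)],
            impute_vars=impute_vars,
            predictors=predictors,
            config=imputation.ImputationConfig(
                m=m, k_donors=k_donors, iterations=iterations, seed=seed
            ),
        )
    else:
        completed = [work] * m

    qaly_ests, cost_ests, rows = [], [], []
    n_complete = len(frame)
    for i, table in enumerate(completed):
        table = table.copy()
        table["qaly"] = valuation.qaly_auc_frame(table, discount_rate=discount_rate)
        table["total_cost"] = resources.total_24m_cost_frame(
            table, intervention_cost=intervention_cost, discount_rate=discount_rate
        )
        dq, vq = cea.adjusted_increment(
            table, "qaly", covariates=covariates, family="gaussian_identity"
        )
        dc, vc = cea.adjusted_increment(
            table, "total_cost", covariates=covariates, family="gaussian_identity"
        )
        qaly_ests.append((dq, vq))
        cost_ests.append((dc, vc))
        rows.append({"imputation": i, "delta_qaly": dq, "delta_cost": dc})

    df_complete = n_complete - (len(covariates) + 2)
    pooled_qaly = imputation.pool_estimates(qaly_ests, df_complete=df_complete)
    pooled_cost = imputation.pool_estimates(cost_ests, df_complete=df_complete)
    estimate = cea.CEEstimate(
        delta_cost=pooled_cost.estimate,
        delta_qaly=pooled_qaly.estimate,
        ci_cost=(pooled_cost.ci_low, pooled_cost.ci_high),
        ci_qaly=(pooled_qaly.ci_low, pooled_qaly.ci_high),
        icer=cea.classify_icer(
            pooled_cost.estimate, pooled_qaly.estimate, rounding=icer_rounding
        ),
    )
    return WithinTrialResult(
        ce=estimate,
        pooled_qaly=pooled_qaly,
        pooled_cost=pooled_cost,
        per_imputation=pd.DataFrame(rows),
        m=m,
    )


def control_state_value_data(
    frame: pd.DataFrame, discount_rate: float = 0.035
) -> pd.DataFrame:
    """Control-arm (SPPB, annual cost, utility) pairs for state-value fitting.

    Year 1 pairs the 0-12-month cost with the 12-month SPPB and utility;
    year 2 pairs the (gap-imputed) 12-24-month cost with the 24-month
    values.  Rows with missing components are dropped (the caller may
    instead pass a completed imputation).
    """
    ctl = frame[frame["arm"] == 0]
    rows = []
    for _, row in ctl.iterrows():
        c06, c612, c1824 = row["cost_0_6"], row["cost_6_12"], row["cost_18_24"]
        if not (np.isnan(c06) or np.isnan(c612) or np.isnan(row["u_12"])):
            rows.append(
                {
                    "sppb": row["sppb_12"],
                    "annual_cost": c06 + c612,
                    "utility": row["u_12"],
                }
            )
        if not (np.isnan(c612) or np.isnan(c1824) or np.isnan(row["u_24"])):
            gap = (c612 + c1824) / 2.0
            rows.append(
                {
                    "sppb": row["sppb_24"],
                    "annual_cost": gap + c1824,
                    "utility": row["u_24"],
                }
            )
    return pd.DataFrame(rows)


def control_transition_panel(frame: pd.DataFrame) -> pd.DataFrame:
    """Annual SPPB transitions (0->12 and 12->24 months) from the control arm."""
    ctl = frame[frame["arm"] == 0]
    parts = []
    for start, end in ((0, 12), (12, 24)):
        parts.append(
            pd.DataFrame(
                {
                    "sppb": ctl[f"sppb_{start}"].to_numpy(),
                    "sppb_next": ctl[f"sppb_{end}"].to_numpy(),
                    "age": ctl["age"].to_numpy() + start / 12.0,
                    "female": ctl["female"].to_numpy(),
                }
            )
        )
    return pd.concat(parts, ignore_index=True).dropna()
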