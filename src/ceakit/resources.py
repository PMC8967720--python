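"""Resource-use costing over the 24-month follow-up.

Six-month recall questionnaires cover 0-6, 6-12 and 18-24 months (plus a
baseline recall); the unmeasured 12-18-month period is imputed as the
mean of its neighbours.  Second-year costs are discounted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

PERIODS = ("baseline", "0-6", "6-12", "12-18", "18-24")

DEFAULT_DISCOUNT_RATE = 0.035


@dataclass
class UnitCostTable:
    """Unit costs (GBP) per resource item, NHS/PSS perspective."""

    prices: dict[str, float]
    price_year: str = "2018-19"
    currency: str = "GBP"

    def __post_init__(self) -> None:
        for item, price in self.prices.items():
            if price < 0:
                raise ValueError(f"negative unit cost for {item!r}")

    def __getitem__(self, item: str) -> float:
        return self.prices[item]

    @classmethod
    def from_csv(cls, path: str | Path) -> "UnitCostTable":
        frame = pd.read_csv(path, comment="#")
        price_year = (
            str(frame["price_year"].iloc[0]) if "price_year" in frame else "2018-19"
        )
        return cls(
            prices=dict(zip(frame["item"], frame["unit_cost"].astype(float))),
            price_year=price_year,
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "item": list(self.prices),
                "unit_cost": list(self.prices.values()),
                "price_year": self.price_year,
            }
        ).to_csv(path, index=False)


def period_cost(counts: Mapping[str, float], prices: UnitCostTable) -> float:
    """Cost of one recall period: sum of count x unit cost.

    Every observed item must be priced; an unpriced item raises (no
    silent zero).  Missing (NaN) counts also raise: the record should be
    completed by imputation first.
    """
    total = 0.0
    for item, count in counts.items():
        if item not in prices.prices:
            raise KeyError(f"resource item {item!r} has no unit cost")
        count = float(count)
        if math.isnan(count):
            raise ValueError(f"missing count for {item!r}; impute before costing")
        if count < 0:
            raise ValueError(f"negative count for {item!r}")
        total += count * prices[item]
    return total


def impute_gap_period(cost_6_12: float, cost_18_24: float) -> float:
    """The unmeasured 12-18-month cost: mean of the neighbouring periods."""
    for label, value in (("6-12", cost_6_12), ("18-24", cost_18_24)):
        if value is None or math.isnan(float(value)):
            raise ValueError(
                f"period {label} cost missing; run multiple imputation before "
                "the gap-period rule"
            )
    return (float(cost_6_12) + float(cost_18_24)) / 2.0


def total_24m_cost(
    cost_0_6: float,
    cost_6_12: float,
    cost_12_18: float,
    cost_18_24: float,
    intervention_cost: float = 0.0,
    discount_rate: float = DEFAULT_DISCOUNT_RATE,
) -> float:
    """Discounted 24-month total cost.

    Year-1 periods and the intervention cost are undiscounted; year-2
    periods are divided by (1 + r).
    """
    periods = (cost_0_6, cost_6_12, cost_12_18, cost_18_24)
    if any(float(c) < 0 for c in periods):
        raise ValueError("period costs must be >= 0")
    year1 = float(cost_0_6) + float(cost_6_12)
    year2 = (float(cost_12_18) + float(cost_18_24)) / (1.0 + discount_rate)
    return year1 + year2 + float(intervention_cost)


def total_24m_cost_frame(
    frame: pd.DataFrame,
    intervention_cost: float = 0.0,
    arm_col: str = "arm",
    discount_rate: float = DEFAULT_DISCOUNT_RATE,
) -> pd.Series:
    """Vectorised 24-month totals from cost_0_6 / cost_6_12 / cost_18_24.

    The 12-18-month gap is imputed row-wise as the neighbour mean; the
    intervention cost is added for rows with ``arm == 1`` only.
    """
    c06 = frame["cost_0_6"].to_numpy(dtype=float)
    c612 = frame["cost_6_12"].to_numpy(dtype=float)
    c1824 = frame["cost_18_24"].to_numpy(dtype=float)
    if np.isnan(np.concatenate([c06, c612, c1824])).any():
        raise ValueError("missing period costs; impute before totalling")
    gap = (c612 + c1824) / 2.0
    arm = frame[arm_col].to_numpy(dtype=float)
    total = c06 + c612 + (gap + c1824) / (1.0 + discount_rate) + intervention_cost * arm
    return pd.Series(total, index=frame.index, name="total_cost")


def costs_from_counts(
    frame: pd.DataFrame,
    prices: UnitCostTable,
    items: list[str],
    period_suffixes: Mapping[str, str] = {
        "cost_base": "base",
        "cost_0_6": "0_6",
        "cost_6_12": "6_12",
        "cost_18_24": "18_24",
    },
) -> pd.DataFrame:
    """Per-period cost columns from per-item count columns.

    Count columns are named ``{item}_{suffix}``.  A period with any
    missing count yields a missing period cost (periods are reported as
    a block by the questionnaire, so item-level missingness is not
    modelled separately).
    """
    out = frame.copy()
    for cost_col, suffix in period_suffixes.items():
        cols = [f"{item}_{suffix}" for item in items]
        counts = frame[cols].to_numpy(dtype=float)
        price_vec = np.array([prices[item] for item in items])
        cost = counts @ price_vec
        cost[np.isnan(counts).any(axis=1)] = np.nan
        out[cost_col] = cost
    return out
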