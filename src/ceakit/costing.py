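"""Micro-costing of a group-delivered programme.

Builds a per-group / per-participant cost breakdown from resource lines
(component, basis, quantity, unit cost), with equivalent-annual-cost
annuitization for capital items and sharing rules for costs split across
several programmes.  All arithmetic is exact Decimal; see
:mod:`ceakit.money`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .money import MoneyLike, as_decimal, round_money

BASES = frozenset(
    {"per_session", "per_participant", "per_group", "per_programme_share"}
)

#: default working-day length used to convert "days" quantities to hours
HOURS_PER_DAY = Decimal("7")


@dataclass(frozen=True)
class CostComponent:
    """One resource line of a costing specification.

    ``quantity`` is in hours (or items); durations given in minutes or
    days must be converted before construction (the YAML loader does
    this).  ``share_divisor`` is the number of programmes the cost is
    shared between (e.g. one training course serving four programmes of
    four trainees each gives a divisor of 16).
    """

    label: str
    basis: str
    quantity: Decimal
    unit_cost: Decimal
    share_divisor: int = 1

    def __post_init__(self) -> None:
        if self.basis not in BASES:
            raise ValueError(f"unknown basis {self.basis!r}; expected one of {sorted(BASES)}")
        object.__setattr__(self, "quantity", as_decimal(self.quantity))
        object.__setattr__(self, "unit_cost", as_decimal(self.unit_cost))
        if self.quantity < 0:
            raise ValueError(f"{self.label}: quantity must be >= 0, got {self.quantity}")
        if self.unit_cost < 0:
            raise ValueError(f"{self.label}: unit_cost must be >= 0, got {self.unit_cost}")
        if self.share_divisor < 1:
            raise ValueError(f"{self.label}: share_divisor must be >= 1")


@dataclass(frozen=True)
class AnnuitySpec:
    """Equivalent-annual-cost specification for a capital item."""

    capital: Decimal
    lifetime_years: int
    discount_rate: Decimal
    timing: str = "in_advance"

    def __post_init__(self) -> None:
        object.__setattr__(self, "capital", as_decimal(self.capital))
        object.__setattr__(self, "discount_rate", as_decimal(self.discount_rate))
        if self.lifetime_years < 1:
            raise ValueError("lifetime_years must be >= 1")
        if not (0 <= self.discount_rate < 1):
            raise ValueError("discount_rate must be in [0, 1)")
        if self.timing not in ("in_advance", "in_arrears"):
            raise ValueError(f"unknown timing {self.timing!r}")


def annuity_factor(rate: MoneyLike, n_years: int, timing: str = "in_advance") -> Decimal:
    """Annuity factor for ``n_years`` annual payments at ``rate``.

    in_arrears: (1 - (1+r)^-n) / r; in_advance multiplies by (1+r).
    r = 0 degenerates to n.
    """
    r = as_decimal(rate)
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    if r == 0:
        return Decimal(n_years)
    one = Decimal(1)
    factor = (one - (one + r) ** -n_years) / r
    if timing == "in_advance":
        factor *= one + r
    elif timing != "in_arrears":
        raise ValueError(f"unknown timing {timing!r}")
    return factor


def annuitize(spec: AnnuitySpec) -> Decimal:
    """Equivalent annual cost of a capital outlay (unrounded Decimal)."""
    return spec.capital / annuity_factor(spec.discount_rate, spec.lifetime_years, spec.timing)


def component_cost(
    component: CostComponent, n_sessions: int, group_size: MoneyLike
) -> Decimal:
    """Per-group cost of one component.

    The basis decides the multiplier: ``per_session`` components scale
    with the number of sessions, ``per_participant`` with the average
    group size, ``per_group`` are flat, and ``per_programme_share`` costs
    are divided between ``share_divisor`` programmes.
    """
    if n_sessions < 0:
        raise ValueError("n_sessions must be >= 0")
    g = as_decimal(group_size)
    if g <= 0:
        raise ValueError("group_size must be > 0")
    q, u = component.quantity, component.unit_cost
    if component.basis == "per_session":
        return q * n_sessions * u
    if component.basis == "per_participant":
        return q * g * u
    if component.basis == "per_group":
        return q * u
    # per_programme_share
    return q * u / component.share_divisor


@dataclass
class ProgrammeCosting:
    """Aggregated costing: per-group and per-participant totals."""

    components: list[tuple[CostComponent, Decimal]]
    group_size: Decimal
    total_per_group: Decimal = field(init=False)
    total_per_participant: Decimal = field(init=False)

    def __post_init__(self) -> None:
        self.group_size = as_decimal(self.group_size)
        if self.group_size <= 0:
            raise ValueError("group_size must be > 0")
        self.total_per_group = sum(
            (cost for _, cost in self.components), start=Decimal(0)
        )
        self.total_per_participant = self.total_per_group / self.group_size

    def per_group(self, label: str) -> Decimal:
        for comp, cost in self.components:
            if comp.label == label:
                return cost
        raise KeyError(label)

    def to_frame(self) -> pd.DataFrame:
        """Report table with penny-rounded columns (presentation only)."""
        rows = [
            {
                "label": comp.label,
                "basis": comp.basis,
                "quantity": float(comp.quantity),
                "unit_cost": float(round_money(comp.unit_cost)),
                "cost_per_group": float(round_money(cost)),
                "cost_per_participant": float(round_money(cost / self.group_size)),
            }
            for comp, cost in self.components
        ]
        rows.append(
            {
                "label": "Total",
                "basis": "",
                "quantity": float("nan"),
                "unit_cost": float("nan"),
                "cost_per_group": float(round_money(self.total_per_group)),
                "cost_per_participant": float(round_money(self.total_per_participant)),
            }
        )
        return pd.DataFrame(rows)


def programme_cost(
    components: Iterable[CostComponent], n_sessions: int, group_size: MoneyLike
) -> ProgrammeCosting:
    """Cost every component and aggregate to group/participant totals."""
    costed = [(c, component_cost(c, n_sessions, group_size)) for c in components]
    return ProgrammeCosting(components=costed, group_size=as_decimal(group_size))


_UNIT_TO_HOURS = {"hours": Decimal(1), "minutes": Decimal(1) / Decimal(60)}


def load_costing_spec(path: str | Path) -> list[CostComponent]:
    """Read a costing specification from YAML.

    Each component row carries label, basis, quantity, unit (hours /
    minutes / days / items), unit_cost and optional share_divisor.  A
    capital item may instead give an ``annuity`` block (capital,
    lifetime_years, discount_rate, timing) whose equivalent annual cost
    becomes the unit cost.  ``hours_per_day`` at the top level controls
    day-to-hour conversion (default 7).
    """
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    hours_per_day = as_decimal(spec.get("hours_per_day", HOURS_PER_DAY))
    components = []
    for row in spec["components"]:
        unit = row.get("unit", "hours")
        quantity = as_decimal(row["quantity"])
        if unit in _UNIT_TO_HOURS:
            quantity *= _UNIT_TO_HOURS[unit]
        elif unit == "days":
            quantity *= hours_per_day
        elif unit != "items":
            raise ValueError(f"unknown quantity unit {unit!r}")
        if "annuity" in row:
            ann = row["annuity"]
            unit_cost = annuitize(
                AnnuitySpec(
                    capital=ann["capital"],
                    lifetime_years=int(ann["lifetime_years"]),
                    discount_rate=ann.get("discount_rate", 0.035),
                    timing=ann.get("timing", "in_advance"),
                )
            )
        else:
            unit_cost = as_decimal(row["unit_cost"])
        components.append(
            CostComponent(
                label=row["label"],
                basis=row["basis"],
                quantity=quantity,
                unit_cost=unit_cost,
                share_divisor=int(row.get("share_divisor", 1)),
            )
        )
    return components


def default_costing_spec_path() -> Path:
    """Path to the packaged 15-line delivery costing specification."""
    return Path(__file__).parent / "data" / "programme_costing.yaml"
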