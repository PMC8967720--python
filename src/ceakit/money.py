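"""Exact money arithmetic.

Programme costing is carried out in :class:`decimal.Decimal` so that
per-group costs are exact to the penny; rounding (half-up) happens only
when a figure is rendered for a report.  Statistical cost quantities
elsewhere in the package (resource-use costs, bootstrap draws) use floats.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

PENNY = Decimal("0.01")

MoneyLike = Decimal | int | float | str


def as_decimal(x: MoneyLike) -> Decimal:
    """Convert a number to an exact Decimal.

    Floats are routed through ``str`` so that a literal like ``29.43``
    becomes exactly ``Decimal('29.43')`` rather than its binary expansion.
    """
    if isinstance(x, Decimal):
        return x
    return Decimal(str(x))


def round_money(x: MoneyLike) -> Decimal:
    """Round to the penny, half-up (presentation rounding)."""
    return as_decimal(x).quantize(PENNY, rounding=ROUND_HALF_UP)
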