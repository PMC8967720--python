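"""Health-state valuation: value-set lookup and discounted QALY AUC.

Utilities come from external value-set lookup tables (one utility per
descriptive-system profile); this module never re-derives a tariff.
QALYs over the 24-month follow-up are the area under the utility curve
with measurement points at months 0, 6, 12 and 24, the second year
discounted as a block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: dimension count and per-dimension level counts for each instrument
INSTRUMENTS: dict[str, tuple[int, ...]] = {
    "EQ5D5L": (5, 5, 5, 5, 5),
    "EQ5D3L": (3, 3, 3, 3, 3),
    "SF6D": (6, 4, 5, 6, 5, 5),
}

#: assessment timepoints in months after randomisation
TIMEPOINTS = (0, 6, 12, 24)

DEFAULT_DISCOUNT_RATE = 0.035


@dataclass(frozen=True)
class HealthProfile:
    """A descriptive-system health state, e.g. EQ-5D ``(1, 2, 1, 1, 3)``."""

    instrument: str
    levels: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.instrument not in INSTRUMENTS:
            raise ValueError(f"unknown instrument {self.instrument!r}")
        maxima = INSTRUMENTS[self.instrument]
        if len(self.levels) != len(maxima):
            raise ValueError(
                f"{self.instrument} profile needs {len(maxima)} dimensions, "
                f"got {len(self.levels)}"
            )
        for level, hi in zip(self.levels, maxima):
            if not 1 <= level <= hi:
                raise ValueError(
                    f"level {level} outside 1..{hi} for {self.instrument}"
                )

    @classmethod
    def from_key(cls, instrument: str, key: str) -> "HealthProfile":
        """Parse a hyphenated profile key like ``'1-2-1-1-3'``."""
        return cls(instrument, tuple(int(t) for t in key.split("-")))

    @property
    def key(self) -> str:
        return "-".join(str(level) for level in self.levels)


@dataclass
class ValueSetTable:
    """Lookup table mapping every profile of an instrument to a utility."""

    instrument: str
    mapping: dict[tuple[int, ...], float]
    floor: float

    def __post_init__(self) -> None:
        maxima = INSTRUMENTS[self.instrument]
        full = tuple(1 for _ in maxima)
        if full in self.mapping and abs(self.mapping[full] - 1.0) > 1e-12:
            raise ValueError("full-health profile must map to utility 1.0")
        for levels, u in self.mapping.items():
            if not (self.floor - 1e-12 <= u <= 1.0 + 1e-12):
                raise ValueError(
                    f"utility {u} for profile {levels} outside [{self.floor}, 1.0]"
                )

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {"profile": "-".join(map(str, levels)), "utility": u}
            for levels, u in sorted(self.mapping.items())
        ]
        frame = pd.DataFrame(rows)
        with open(path, "w") as fh:
            fh.write(f"# instrument={self.instrument} floor={self.floor}\n")
            frame.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ValueSetTable":
        with open(path) as fh:
            header = fh.readline().strip().lstrip("#").split()
            meta = dict(item.split("=") for item in header)
            frame = pd.read_csv(fh)
        mapping = {
            tuple(int(t) for t in key.split("-")): float(u)
            for key, u in zip(frame["profile"], frame["utility"])
        }
        return cls(meta["instrument"], mapping, float(meta["floor"]))


def lookup_utility(profile: HealthProfile, value_set: ValueSetTable) -> float:
    """Tabulated utility for one profile; errors name the missing profile."""
    if profile.instrument != value_set.instrument:
        raise ValueError(
            f"profile instrument {profile.instrument} does not match "
            f"value set instrument {value_set.instrument}"
        )
    try:
        return value_set.mapping[profile.levels]
    except KeyError:
        raise KeyError(
            f"profile {profile.key} absent from {value_set.instrument} value set"
        ) from None


@dataclass
class UtilityTrajectory:
    """Utilities for one participant at months 0/6/12/24."""

    participant: str | int
    utilities: Mapping[int, float]
    discount_rate: float = DEFAULT_DISCOUNT_RATE

    def __post_init__(self) -> None:
        missing = [t for t in TIMEPOINTS if t not in self.utilities]
        if missing:
            raise ValueError(f"trajectory missing timepoints {missing}")


def qaly_weights(discount_rate: float = DEFAULT_DISCOUNT_RATE) -> np.ndarray:
    """Trapezoid weights on the (u0, u6, u12, u24) utility vector.

    Months 0-12 are undiscounted; the 12-24-month trapezoid is divided
    by (1 + r) as a block (year-2 discount).
    """
    d = 1.0 / (1.0 + discount_rate)
    return np.array([0.25, 0.5, 0.25 + 0.5 * d, 0.5 * d])


def qaly_auc(traj: UtilityTrajectory) -> float:
    """Discounted QALYs over 24 months by the area-under-the-curve method.

    Raises if any utility is missing: imputation must happen upstream.
    """
    u = np.array([traj.utilities[t] for t in TIMEPOINTS], dtype=float)
    if np.isnan(u).any():
        raise ValueError(
            f"participant {traj.participant}: missing utilities; impute before "
            "computing QALYs"
        )
    return float(qaly_weights(traj.discount_rate) @ u)


def qaly_auc_frame(
    frame: pd.DataFrame,
    columns: Sequence[str] = ("u_0", "u_6", "u_12", "u_24"),
    discount_rate: float = DEFAULT_DISCOUNT_RATE,
) -> pd.Series:
    """Vectorised :func:`qaly_auc` over a participant table."""
    u = frame[list(columns)].to_numpy(dtype=float)
    if np.isnan(u).any():
        raise ValueError("missing utilities; impute before computing QALYs")
    return pd.Series(u @ qaly_weights(discount_rate), index=frame.index, name="qaly")
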