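"""Smaller-the-better desirability scoring of the raw (TC, ST) responses.

Each response is linearly normalized into [0, 1] against bounds taken from
the observed results table: d1 for total cost, d2 for system time, both 1 at
or below the lower bound and 0 at or above the upper bound.  The combined
per-row desirability is the product d = d1 * d2, the quantity the surrogate
network is trained to predict.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DesirabilityBounds", "bounds_from_results", "d1_of", "d2_of",
           "combine", "score_table"]


@dataclass(frozen=True)
class DesirabilityBounds:
    """Normalization bounds for the two responses."""

    tc_min: float
    tc_max: float
    st_min: float
    st_max: float

    def __post_init__(self):
        if not self.tc_min < self.tc_max:
            raise ValueError(f"need TC_min < TC_max, got [{self.tc_min}, {self.tc_max}]")
        if not self.st_min < self.st_max:
            raise ValueError(f"need ST_min < ST_max, got [{self.st_min}, {self.st_max}]")

    def to_dict(self) -> dict:
        return {"tc_min": self.tc_min, "tc_max": self.tc_max,
                "st_min": self.st_min, "st_max": self.st_max}

    @classmethod
    def from_dict(cls, d) -> "DesirabilityBounds":
        return cls(float(d["tc_min"]), float(d["tc_max"]),
                   float(d["st_min"]), float(d["st_max"]))


def bounds_from_results(table: pd.DataFrame) -> DesirabilityBounds:
    """Global observed min/max of TC and ST across the whole results table."""
    if not len(table):
        raise ValueError("results table is empty")
    tc_min, tc_max = float(table["TC"].min()), float(table["TC"].max())
    st_min, st_max = float(table["ST"].min()), float(table["ST"].max())
    if tc_min == tc_max:
        raise ValueError("TC column is constant; desirability bounds degenerate")
    if st_min == st_max:
        raise ValueError("ST column is constant; desirability bounds degenerate")
    return DesirabilityBounds(tc_min, tc_max, st_min, st_max)


def _stb(value, lo: float, hi: float):
    """Linear smaller-the-better map: 1 below lo, 0 above hi."""
    value = np.asarray(value, dtype=float)
    with np.errstate(invalid="ignore"):
        d = (value - hi) / (lo - hi)
    d = np.clip(d, 0.0, 1.0)
    return float(d) if d.ndim == 0 else d

def d1_of(tc, bounds: DesirabilityBounds):
    """Cost desirability: 1 at TC <= TC_min, linear in between, 0 at TC >= TC_max."""
    return _stb(tc, bounds.tc_min, bounds.tc_max)


def d2_of(st, bounds: DesirabilityBounds):
    """Time desirability: 1 at ST <= ST_min, linear in between, 0 at ST >= ST_max."""
    return _stb(st, bounds.st_min, bounds.st_max)


def combine(d1, d2):
    """Multiplicative combination d = d1 * d2 of the two desirabilities."""
    d1a = np.asarray(d1, dtype=float)
    d2a = np.asarray(d2, dtype=float)
    if np.any(d1a < 0) or np.any(d1a > 1) or np.any(d2a < 0) or np.any(d2a > 1):
        raise ValueError("desirabilities must lie in [0, 1]")
    out = d1a * d2a
    return float(out) if out.ndim == 0 else out


def score_table(table: pd.DataFrame,
                bounds: DesirabilityBounds | None = None) -> tuple[pd.DataFrame, DesirabilityBounds]:
    """Augment a results table with per-row d1, d2 and d = d1*d2.

    Bounds default to the table's own global min/max so scores are comparable
    across settings and outer cells.  Returns (scored copy, bounds used).
    """
    if bounds is None:
        bounds = bounds_from_results(table)
    scored = table.copy()
    scored["d1"] = d1_of(scored["TC"].to_numpy(), bounds)
    scored["d2"] = d2_of(scored["ST"].to_numpy(), bounds)
    scored["d"] = combine(scored["d1"].to_numpy(), scored["d2"].to_numpy())
    return scored, bounds
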