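"""One-factor sensitivity sweep around the optimized setting.

Each factor is perturbed over the integers between its nearest configured
level below the optimum and its nearest level above it, holding the other
three factors at their optimal values; when the optimum sits on a boundary
level the sweep is one-sided.  Rows report the surrogate's predicted
desirability and the adjusted d%, the percentage change relative to the
optimum — 0 exactly at the optimum, and non-positive everywhere whenever the
optimum is the verified box maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scenario import FACTOR_LETTERS, FACTOR_NAMES, ControlSetting, FactorLevels
from .optimizer_ga import OptimResult
from .surrogate_nn import SurrogateModel

__all__ = ["SensitivityRow", "adjusted_d_pct", "sweep", "impact_power",
           "render_table"]


@dataclass(frozen=True)
class SensitivityRow:
    factor: str          # A | B | C | D
    value: int
    d_hat: float
    adj_d_pct: float


def adjusted_d_pct(d_level: float, d_opt: float) -> float:
    """Adjusted d% = 100 * (d_level - d_opt) / d_opt."""
    if d_opt <= 0:
        raise ValueError(f"optimum desirability must be > 0, got {d_opt}")
    return 100.0 * (d_level - d_opt) / d_opt


def _sweep_range(levels: tuple[int, int, int], opt: int,
                 steps: int | None) -> range:
    """Integers to evaluate for one factor.

    Default: from the nearest level value below the optimum to the nearest
    level value above it; one-sided when the optimum equals a boundary level.
    ``steps`` overrides with a fixed-width window opt +/- steps, clipped to
    [level1, level3].
    """
    lo_bound, hi_bound = levels[0], levels[2]
    if not lo_bound <= opt <= hi_bound:
        raise ValueError(f"optimum {opt} outside levels {levels}")
    if steps is not None:
        if steps < 0:
            raise ValueError("steps must be >= 0")
        return range(max(opt - steps, lo_bound), min(opt + steps, hi_bound) + 1)
    below = [v for v in levels if v < opt]
    above = [v for v in levels if v > opt]
    start = max(below) if below else opt
    stop = min(above) if above else opt
    return range(start, stop + 1)


def sweep(model: SurrogateModel, optimum: OptimResult, levels: FactorLevels,
          steps: int | None = None) -> pd.DataFrame:
    """Evaluate the one-factor perturbations and the adjusted d% table."""
    opt_vals = optimum.best_setting.as_tuple()
    d_opt = model.predict(optimum.best_setting)
    rows: list[SensitivityRow] = []
    for fi, (letter, name) in enumerate(zip(FACTOR_LETTERS, FACTOR_NAMES)):
        for v in _sweep_range(levels.levels_of(name), opt_vals[fi], steps):
            if v == opt_vals[fi]:
                d_hat, adj = d_opt, 0.0
            else:
                trial = list(opt_vals)
                trial[fi] = v
                d_hat = model.predict(ControlSetting.from_tuple(trial))
                adj = adjusted_d_pct(d_hat, d_opt)
            rows.append(SensitivityRow(letter, int(v), d_hat, adj))
    return pd.DataFrame([r.__dict__ for r in rows])


def impact_power(sweep_table: pd.DataFrame) -> pd.DataFrame:
    """Per-factor impact power: the largest |adjusted d%| seen in its sweep.

    Returned sorted ascending, mirroring a 'factor X matters least ... most'
    reading; specific to the run's own parameters.
    """
    rows = []
    for letter, grp in sweep_table.groupby("factor", sort=True):
        rows.append({"factor": letter,
                     "impact_power": float(grp["adj_d_pct"].abs().max())})
    return (pd.DataFrame(rows)
            .sort_values("impact_power", kind="stable")
            .reset_index(drop=True))


def render_table(sweep_table: pd.DataFrame) -> str:
    """Plain-text rendering, one pair of lines (values, adjusted d%) per factor."""
    lines = []
    for letter in sorted(sweep_table["factor"].unique()):
        grp = sweep_table[sweep_table["factor"] == letter]
        vals = "\t".join(str(int(v)) for v in grp["value"])
        dpct = "\t".join("0" if a == 0 else f"{a:.2f}" for a in grp["adj_d_pct"])
        lines.append(f"Factor {letter}\t{vals}")
        lines.append(f"d%\t{dpct}")
    return "\n".join(lines) + "\n"
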