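"""Crossed-array experiment: L9(3^4) inner array x signal/noise outer array.

The nine inner-array runs assign the four control factors to the columns of
the standard L9 orthogonal array.  Each run is crossed with every
(signal, noise) outer combination — target OR utilization x arrival rate —
and replicated; every cell applies its outer condition uniformly across the
simulated week so outer factors are not confounded with day of week.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .scenario import FACTOR_LETTERS, FACTOR_NAMES, ControlSetting, FactorLevels, ScenarioConfig
from .simulator import simulate_week

__all__ = ["L9_ARRAY", "DesignMatrix", "build_l9", "run_design", "RESULT_COLUMNS"]

logger = logging.getLogger(__name__)

#: Standard L9(3^4) orthogonal array, canonical Taguchi row order,
#: 1-based level indices.
L9_ARRAY = np.array([
    [1, 1, 1, 1],
    [1, 2, 2, 2],
    [1, 3, 3, 3],
    [2, 1, 2, 3],
    [2, 2, 3, 1],
    [2, 3, 1, 2],
    [3, 1, 3, 2],
    [3, 2, 1, 3],
    [3, 3, 2, 1],
], dtype=np.int64)

RESULT_COLUMNS = ["setting_id", *FACTOR_LETTERS, "utilization", "arrival_rate",
                  "replicate", "TC", "ST", "n_completed", "n_dropped"]


@dataclass(frozen=True)
class DesignMatrix:
    """The realized inner array: level indices plus integer factor values."""

    indices: np.ndarray            # 9 x 4, level indices 1..3
    settings: tuple[ControlSetting, ...]

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        """Assert L9 shape, per-column level balance, pairwise orthogonality."""
        idx = self.indices
        if idx.shape != (9, 4):
            raise ValueError(f"L9 design must be 9x4, got {idx.shape}")
        if len(self.settings) != 9:
            raise ValueError("need exactly 9 realized settings")
        for col in range(4):
            counts = np.bincount(idx[:, col], minlength=4)[1:]
            if not np.all(counts == 3):
                raise ValueError(
                    f"column {FACTOR_LETTERS[col]} unbalanced: {counts.tolist()}")
        for c1, c2 in product(range(4), repeat=2):
            if c1 >= c2:
                continue
            pairs = {(int(a), int(b)) for a, b in zip(idx[:, c1], idx[:, c2])}
            if len(pairs) != 9:
                raise ValueError(
                    f"columns {FACTOR_LETTERS[c1]},{FACTOR_LETTERS[c2]} "
                    "not orthogonal: duplicate level pairs")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, (lv, s) in enumerate(zip(self.indices, self.settings), start=1):
            rows.append({"setting_id": i,
                         **{f"level_{l}": int(v) for l, v in zip(FACTOR_LETTERS, lv)},
                         **{l: v for l, v in zip(FACTOR_LETTERS, s.as_tuple())}})
        return pd.DataFrame(rows)


def build_l9(levels: FactorLevels) -> DesignMatrix:
    """Map the standard L9 array onto the configured integer factor levels."""
    settings = tuple(levels.setting_from_indices(row) for row in L9_ARRAY)
    return DesignMatrix(indices=L9_ARRAY.copy(), settings=settings)


def cell_rng(seed: int, setting_id: int, signal_idx: int, noise_idx: int,
             replicate: int) -> np.random.Generator:
    """Independent, reproducible random stream for one (cell, replicate)."""
    ss = np.random.SeedSequence(entropy=seed,
                                spawn_key=(setting_id, signal_idx, noise_idx,
                                           replicate))
    return np.random.default_rng(ss)


def run_design(config: ScenarioConfig, *, replicates: int | None = None,
               progress: bool = False) -> pd.DataFrame:
    """Execute the full crossed design and collect the raw results table.

    Every (inner run, signal, noise) cell is simulated ``replicates`` times
    (default: ``config.replicates``), with the outer condition held uniform
    over the week.  Deterministic for a given ``config.seed``: each cell
    replicate draws from its own seeded stream.
    """
    reps = config.replicates if replicates is None else int(replicates)
    if reps < 1:
        raise ValueError("replicates must be >= 1")
    design = build_l9(config.factor_levels)
    signals = config.signal_levels
    noises = config.noise_levels
    rows = []
    n_cells = 9 * len(signals) * len(noises)
    done = 0
    for sid, setting in enumerate(design.settings, start=1):
        for gi, sig in enumerate(signals):
            for ni, noi in enumerate(noises):
                for rep in range(reps):
                    rng = cell_rng(config.seed, sid, gi, ni, rep)
                    try:
                        out = simulate_week(
                            config, setting, rng,
                            regime_override=(sig.utilization, noi.arrival_rate))
                    except Exception as exc:
                        raise RuntimeError(
                            f"simulation failed in cell setting={sid} "
                            f"utilization={sig.utilization} "
                            f"arrival_rate={noi.arrival_rate} replicate={rep}"
                        ) from exc
                    a, b, c, d = setting.as_tuple()
                    rows.append((sid, a, b, c, d, sig.utilization,
                                 noi.arrival_rate, rep, out.tc, out.st,
                                 out.n_completed, out.n_dropped))
                done += 1
                if progress:
                    logger.info("cell %d/%d done (setting %d, u=%.2f, lam=%g)",
                                done, n_cells, sid, sig.utilization,
                                noi.arrival_rate)
    table = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if (table["TC"] < 0).any() or (table["ST"] < 0).any():
        raise RuntimeError("negative TC/ST in results table")
    return table
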