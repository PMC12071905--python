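"""Feedforward surrogate mapping a control setting to predicted desirability.

A single-hidden-layer network (4 inputs — the factor values, min-max scaled
to [0,1]; logistic activations throughout; 1 sigmoid output) is trained by
full-batch gradient descent on squared error with momentum 0.75 for 10,000
epochs.  The learning rate self-adjusts within [0.01, 0.25] by a bold-driver
rule (grow 5% after an epoch that lowers the loss, shrink 30% and cancel the
velocity after one that raises it).  Hidden-layer width is selected by test
RMSE over candidate widths 1..6 on a shared stratified train/test split.

Training rows are per-replicate (setting, d) pairs, so the replicate spread
across the signal/noise outer cells is absorbed as target noise and the
fitted response is a robustness-averaged desirability.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .scenario import FACTOR_LETTERS, ControlSetting

__all__ = ["NNStructure", "SurrogateModel", "TrainReport", "DivergenceError",
           "split_train_test", "train", "select_structure", "predict", "rmse"]

logger = logging.getLogger(__name__)

LEARNING_RATE_MIN = 0.01
LEARNING_RATE_MAX = 0.25
MOMENTUM = 0.75
DEFAULT_EPOCHS = 10_000
INIT_HALF_WIDTH = 0.5


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""


@dataclass(frozen=True)
class NNStructure:
    """(input, hidden, output) node counts; inputs and output are fixed."""

    hidden_nodes: int
    input_nodes: int = 4
    output_nodes: int = 1

    def __post_init__(self):
        if self.input_nodes != 4 or self.output_nodes != 1:
            raise ValueError("structure must be 4-h-1")
        if not 1 <= self.hidden_nodes <= 6:
            raise ValueError(f"hidden nodes must be in 1..6, got {self.hidden_nodes}")

    def label(self) -> str:
        return f"{self.input_nodes}, {self.hidden_nodes}, {self.output_nodes}"


@dataclass(frozen=True)
class TrainReport:
    structure: NNStructure
    rmse_train: float
    rmse_test: float
    final_learning_rate: float
    seed: int


@dataclass
class SurrogateModel:
    """Trained network weights plus the input scaling they were fit under."""

    structure: NNStructure
    w1: np.ndarray          # (4, h)
    b1: np.ndarray          # (h,)
    w2: np.ndarray          # (h,)
    b2: float
    x_min: np.ndarray       # (4,)
    x_max: np.ndarray       # (4,)
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def _scale(self, x: np.ndarray) -> np.ndarray:
        span = np.where(self.x_max > self.x_min, self.x_max - self.x_min, 1.0)
        z = (x - self.x_min) / span
        if np.any(z < -1e-9) or np.any(z > 1 + 1e-9):
            logger.warning("setting outside the fitted scaling box; extrapolating")
        return z

    def predict_many(self, x: np.ndarray) -> np.ndarray:
        """Forward pass for an (n, 4) array of settings; returns (n,) in (0,1)."""
        x = np.asarray(x, dtype=float)
        z = self._scale(x)
        h = _sigmoid(z @ self.w1 + self.b1)
        return _sigmoid(h @ self.w2 + self.b2)

    def predict(self, setting: ControlSetting | np.ndarray) -> float:
        if isinstance(setting, ControlSetting):
            x = np.asarray(setting.as_tuple(), dtype=float)
        else:
            x = np.asarray(setting, dtype=float)
        return float(self.predict_many(x[None, :])[0])

    # -- persistence -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "structure": {"input_nodes": 4,
                          "hidden_nodes": self.structure.hidden_nodes,
                          "output_nodes": 1},
            "w1": self.w1.tolist(), "b1": self.b1.tolist(),
            "w2": self.w2.tolist(), "b2": self.b2,
            "x_min": self.x_min.tolist(), "x_max": self.x_max.tolist(),
            "hyperparameters": self.hyperparameters, "seed": self.seed,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "SurrogateModel":
        return cls(
            structure=NNStructure(int(d["structure"]["hidden_nodes"])),
            w1=np.asarray(d["w1"], dtype=float),
            b1=np.asarray(d["b1"], dtype=float),
            w2=np.asarray(d["w2"], dtype=float),
            b2=float(d["b2"]),
            x_min=np.asarray(d["x_min"], dtype=float),
            x_max=np.asarray(d["x_max"], dtype=float),
            hyperparameters=dict(d.get("hyperparameters", {})),
            seed=int(d.get("seed", 0)),
        )

    @classmethod
    def load(cls, path: str | Path) -> "SurrogateModel":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @classmethod
    def random(cls, hidden_nodes: int, x_min, x_max,
               seed: int = 0) -> "SurrogateModel":
        """Random-weight model (no training); useful as a test surface."""
        rng = np.random.default_rng(seed)
        h = hidden_nodes
        return cls(
            structure=NNStructure(h),
            w1=rng.uniform(-2.0, 2.0, size=(4, h)),
            b1=rng.uniform(-2.0, 2.0, size=h),
            w2=rng.uniform(-2.0, 2.0, size=h),
            b2=float(rng.uniform(-2.0, 2.0)),
            x_min=np.asarray(x_min, dtype=float),
            x_max=np.asarray(x_max, dtype=float),
            seed=seed,
        )


def _sigmoid(v):
    return 1.0 / (1.0 + np.exp(-v))


def rmse(predicted, observed) -> float:
    """Root-mean-square error between predictions and observations."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.size == 0:
        raise ValueError("rmse needs two equal-length non-empty vectors")
    return float(np.sqrt(np.mean((predicted - observed) ** 2)))


def predict(model: SurrogateModel, setting: ControlSetting) -> float:
    """Module-level alias for :meth:`SurrogateModel.predict`."""
    return model.predict(setting)


def split_train_test(table: pd.DataFrame, fraction: float = 0.8,
                     seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random disjoint partition stratified by setting_id.

    Every setting present in the table lands in both partitions, so test RMSE
    is never computed on unseen factor combinations.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0,1), got {fraction}")
    if not len(table):
        raise ValueError("cannot split an empty table")
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for sid, group in table.groupby("setting_id", sort=True):
        n = len(group)
        n_train = int(round(fraction * n))
        if n < 2 or n_train < 1 or n_train >= n:
            raise ValueError(
                f"setting {sid} has {n} rows; too few to stratify at "
                f"fraction {fraction}")
        perm = rng.permutation(n)
        train_parts.append(group.iloc[perm[:n_train]])
        test_parts.append(group.iloc[perm[n_train:]])
    return (pd.concat(train_parts).reset_index(drop=True),
            pd.concat(test_parts).reset_index(drop=True))


def _design_arrays(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    x = table[list(FACTOR_LETTERS)].to_numpy(dtype=float)
    y = table["d"].to_numpy(dtype=float)
    return x, y


def train(train_table: pd.DataFrame, structure: NNStructure, seed: int = 0, *,
          test_table: pd.DataFrame | None = None,
          epochs: int = DEFAULT_EPOCHS,
          initial_learning_rate: float = 0.1) -> tuple[SurrogateModel, TrainReport]:
    """Fit one network on per-replicate (setting, d) rows.

    Deterministic for a given seed: weights start uniform(-0.5, 0.5) from the
    seeded stream and the full-batch trajectory has no other randomness.
    """
    if not len(train_table):
        raise ValueError("training set is empty")
    x_raw, y = _design_arrays(train_table)
    if np.any(y < 0) or np.any(y > 1):
        raise ValueError("targets d must lie in [0, 1]")

    x_min = x_raw.min(axis=0)
    x_max = x_raw.max(axis=0)
    span = np.where(x_max > x_min, x_max - x_min, 1.0)
    x = (x_raw - x_min) / span

    rng = np.random.default_rng(seed)
    h = structure.hidden_nodes
    w1 = rng.uniform(-INIT_HALF_WIDTH, INIT_HALF_WIDTH, size=(4, h))
    b1 = rng.uniform(-INIT_HALF_WIDTH, INIT_HALF_WIDTH, size=h)
    w2 = rng.uniform(-INIT_HALF_WIDTH, INIT_HALF_WIDTH, size=h)
    b2 = float(rng.uniform(-INIT_HALF_WIDTH, INIT_HALF_WIDTH))

    v_w1 = np.zeros_like(w1)
    v_b1 = np.zeros_like(b1)
    v_w2 = np.zeros_like(w2)
    v_b2 = 0.0

    n = len(y)
    lr = float(np.clip(initial_learning_rate, LEARNING_RATE_MIN, LEARNING_RATE_MAX))
    prev_loss = np.inf

    for epoch in range(epochs):
        hidden = _sigmoid(x @ w1 + b1)            # (n, h)
        out = _sigmoid(hidden @ w2 + b2)          # (n,)
        err = out - y
        loss = float(np.mean(err ** 2))
        if not np.isfinite(loss):
            raise DivergenceError(f"non-finite loss at epoch {epoch}")

        # bold-driver learning-rate adaptation, clamped to [0.01, 0.25]
        if loss < prev_loss:
            lr = min(lr * 1.05, LEARNING_RATE_MAX)
        else:
            lr = max(lr * 0.7, LEARNING_RATE_MIN)
            v_w1[:] = 0.0; v_b1[:] = 0.0; v_w2[:] = 0.0; v_b2 = 0.0
        prev_loss = loss

        delta_out = err * out * (1.0 - out) * (2.0 / n)      # dL/d(pre-activation)
        g_w2 = hidden.T @ delta_out
        g_b2 = float(delta_out.sum())
        delta_h = np.outer(delta_out, w2) * hidden * (1.0 - hidden)
        g_w1 = x.T @ delta_h
        g_b1 = delta_h.sum(axis=0)

        v_w1 = MOMENTUM * v_w1 - lr * g_w1
        v_b1 = MOMENTUM * v_b1 - lr * g_b1
        v_w2 = MOMENTUM * v_w2 - lr * g_w2
        v_b2 = MOMENTUM * v_b2 - lr * g_b2
        w1 += v_w1; b1 += v_b1; w2 += v_w2; b2 += v_b2

    model = SurrogateModel(
        structure=structure, w1=w1, b1=b1, w2=w2, b2=b2,
        x_min=x_min, x_max=x_max,
        hyperparameters={
            "epochs": epochs, "momentum": MOMENTUM,
            "learning_rate_range": [LEARNING_RATE_MIN, LEARNING_RATE_MAX],
            "final_learning_rate": lr,
        },
        seed=seed,
    )
    rmse_train = rmse(model.predict_many(x_raw), y)
    if test_table is not None and len(test_table):
        xt, yt = _design_arrays(test_table)
        rmse_test = rmse(model.predict_many(xt), yt)
    else:
        rmse_test = float("nan")
    report = TrainReport(structure=structure, rmse_train=rmse_train,
                         rmse_test=rmse_test, final_learning_rate=lr, seed=seed)
    return model, report


def select_structure(scored: pd.DataFrame, candidates=range(1, 7), seed: int = 0, *,
                     fraction: float = 0.8, epochs: int = DEFAULT_EPOCHS
                     ) -> tuple[SurrogateModel, TrainReport, pd.DataFrame]:
    """Train every candidate hidden width on one shared split; keep the best.

    Returns (best model, its report, full report table sorted by candidate).
    The winner minimizes test RMSE; ties break toward fewer hidden nodes.
    """
    candidates = list(candidates)
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate structures")
    train_set, test_set = split_train_test(scored, fraction=fraction, seed=seed)
    rows = []
    best: tuple[SurrogateModel, TrainReport] | None = None
    for h in sorted(candidates):
        model, report = train(train_set, NNStructure(h), seed=seed,
                              test_table=test_set, epochs=epochs)
        rows.append({"structure": report.structure.label(),
                     "hidden_nodes": h,
                     "rmse_train": report.rmse_train,
                     "rmse_test": report.rmse_test,
                     "final_learning_rate": report.final_learning_rate})
        logger.info("structure (%s): train RMSE %.5f, test RMSE %.5f",
                    report.structure.label(), report.rmse_train, report.rmse_test)
        if best is None or report.rmse_test < best[1].rmse_test:
            best = (model, report)
    assert best is not None
    return best[0], best[1], pd.DataFrame(rows)
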