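"""Genetic-algorithm maximization of predicted desirability over the factor box.

Chromosomes are the four integer factor values, constrained to the interval
[level 1, level 3] of each factor.  Operators: size-2 tournament selection,
uniform crossover applied to 85% of parent pairs, per-gene random-reset
mutation at 8%, and elitism (best individuals copied unchanged) so the
best-so-far trajectory is non-decreasing.  A brute-force enumerator over the
full integer box serves as the exactness oracle for moderate box sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .scenario import ControlSetting, FactorLevels
from .surrogate_nn import SurrogateModel

__all__ = ["GAConfig", "OptimResult", "ga_optimize", "brute_force_optimum"]

logger = logging.getLogger(__name__)

Fitness = Callable[[np.ndarray], np.ndarray]


@dataclass(frozen=True)
class GAConfig:
    generations: int = 1000
    population: int = 150
    crossover_rate: float = 0.85
    mutation_rate: float = 0.08
    seed: int = 0
    elitism_count: int = 2

    def __post_init__(self):
        if not 0.0 <= self.crossover_rate <= 1.0:
            raise ValueError("crossover_rate must be in [0,1]")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0,1]")
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if not 0 <= self.elitism_count < self.population:
            raise ValueError("elitism_count must be in [0, population)")


@dataclass
class OptimResult:
    best_setting: ControlSetting
    best_d: float
    history: np.ndarray = field(default_factory=lambda: np.empty(0))

    def to_dict(self) -> dict:
        return {"best_setting": dict(zip("ABCD", self.best_setting.as_tuple())),
                "best_d": self.best_d,
                "history": self.history.tolist()}


def _fitness_fn(model_or_fn) -> Fitness:
    if isinstance(model_or_fn, SurrogateModel):
        return model_or_fn.predict_many
    if callable(model_or_fn):
        return model_or_fn
    raise TypeError("need a SurrogateModel or a callable fitness")


def _bounds_arrays(bounds: FactorLevels) -> tuple[np.ndarray, np.ndarray]:
    sb = bounds.search_bounds
    lo = np.array([v[0] for v in sb.values()], dtype=np.int64)
    hi = np.array([v[1] for v in sb.values()], dtype=np.int64)
    return lo, hi


def ga_optimize(model, bounds: FactorLevels, cfg: GAConfig | None = None) -> OptimResult:
    """Maximize fitness over the integer box; deterministic per cfg.seed.

    ``model`` is a trained :class:`SurrogateModel` or any callable mapping an
    (n, 4) integer array to n fitness values.  Returns the best individual
    ever evaluated along with the per-generation best-so-far history.
    """
    cfg = cfg or GAConfig()
    fitness = _fitness_fn(model)
    lo, hi = _bounds_arrays(bounds)
    if np.any(hi < lo):
        raise ValueError("empty search box")
    rng = np.random.default_rng(cfg.seed)
    pop_n = cfg.population

    pop = rng.integers(lo, hi + 1, size=(pop_n, 4))
    history = np.empty(cfg.generations)
    best_x: np.ndarray | None = None
    best_f = -np.inf

    for gen in range(cfg.generations):
        f = np.asarray(fitness(pop), dtype=float)
        gen_best = int(np.argmax(f))
        if f[gen_best] > best_f:
            best_f = float(f[gen_best])
            best_x = pop[gen_best].copy()
        history[gen] = best_f

        if gen == cfg.generations - 1:
            break

        # elitism: carry the current best individuals unchanged
        elite_idx = np.argsort(f)[::-1][:cfg.elitism_count]
        elites = pop[elite_idx].copy()

        # size-2 tournament selection
        n_children = pop_n - cfg.elitism_count
        cand = rng.integers(0, pop_n, size=(n_children, 2))
        winners = np.where(f[cand[:, 0]] >= f[cand[:, 1]], cand[:, 0], cand[:, 1])
        children = pop[winners].copy()

        # uniform crossover on consecutive pairs
        for i in range(0, n_children - 1, 2):
            if rng.random() < cfg.crossover_rate:
                mask = rng.random(4) < 0.5
                a, b = children[i].copy(), children[i + 1].copy()
                children[i][mask], children[i + 1][mask] = b[mask], a[mask]

        # per-gene random-reset mutation within bounds
        mut_mask = rng.random(children.shape) < cfg.mutation_rate
        if mut_mask.any():
            resets = rng.integers(lo, hi + 1, size=children.shape)
            children[mut_mask] = resets[mut_mask]

        pop = np.vstack([elites, children])

    assert best_x is not None
    return OptimResult(best_setting=ControlSetting.from_tuple(best_x),
                       best_d=best_f, history=history)


def brute_force_optimum(model, bounds: FactorLevels,
                        cap: int = 10 ** 6) -> OptimResult:
    """Exhaustive enumeration of the integer box; exact argmax.

    Ties on fitness resolve to the lexicographically smallest setting.  Boxes
    larger than ``cap`` points are refused (use the GA there).
    """
    fitness = _fitness_fn(model)
    lo, hi = _bounds_arrays(bounds)
    size = int(np.prod(hi - lo + 1))
    if size > cap:
        raise ValueError(
            f"box has {size} settings (> cap {cap}); use ga_optimize instead")
    axes = [np.arange(l, h + 1) for l, h in zip(lo, hi)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 4)
    values = np.asarray(fitness(grid), dtype=float)
    vmax = values.max()
    ties = grid[values == vmax]
    # grid is already in lexicographic order, so the first tie is smallest
    best = ties[0]
    return OptimResult(best_setting=ControlSetting.from_tuple(best),
                       best_d=float(vmax), history=np.array([float(vmax)]))
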