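"""Bald Eagle Search: a three-phase swarm optimizer on the unit hypercube.

Each epoch applies, in order,

* **select space** — every agent moves toward the best-known position,
  ``P_new = P_best + alpha * r * (P_mean - P_i)`` with r ~ U[0,1];
* **search space** — spiral-like local exploration,
  ``P_new = P_i + y_i * (P_i - P_{i+1}) + x_i * (P_i - P_mean)`` with
  x_i, y_i ~ U[-1,1] and circular neighbour indexing;
* **swoop** — a dive toward the best solution,
  ``P_new = rand * P_best + x1_i * (P_i - c1 * P_mean) + y1_i * (P_i - c2 * P_best)``.

Candidates are clipped to [0,1]^D and accepted per agent only when strictly
better (greedy elitism), which makes the best-fitness history monotone.
P_mean is the mean of the current population positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

__all__ = ["BESConfig", "SwarmState", "select_space", "search_space", "swoop",
           "optimize", "history_to_csv"]


@dataclass(frozen=True)
class BESConfig:
    """Swarm size, epoch budget and the movement coefficients.

    alpha scales the select-space step and conventionally lies in [1.5, 2];
    c1 and c2 balance the pull of the population mean and the best position
    during the swoop.
    """

    population: int = 30
    epochs: int = 50
    alpha: float = 2.0
    c1: float = 2.0
    c2: float = 2.0
    seed: int = 0
    maximize: bool = True

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("c1 and c2 must be positive")


@dataclass
class SwarmState:
    """Positions, fitnesses and incumbent best of the eagle population."""

    positions: np.ndarray          # (N, D) in [0,1]
    fitnesses: np.ndarray          # (N,)
    best_position: np.ndarray      # (D,)
    best_fitness: float
    epoch: int = 0
    history: list[float] = field(default_factory=list)

    @property
    def mean_position(self) -> np.ndarray:
        return self.positions.mean(axis=0)


def _clip(c: np.ndarray) -> np.ndarray:
    return np.clip(c, 0.0, 1.0)


def select_space(
    state: SwarmState,
    config: BESConfig,
    rng: np.random.Generator | None = None,
    *,
    r: np.ndarray | None = None,
) -> np.ndarray:
    """Select-space candidates: move each agent toward the best region.

    ``r`` may be supplied explicitly (one U[0,1] scalar per agent) for
    deterministic evaluation; otherwise it is drawn from ``rng``.
    """
    n = state.positions.shape[0]
    if r is None:
        r = rng.random(n)
    r = np.asarray(r, dtype=float).reshape(n, 1)
    mean = state.mean_position
    cand = state.best_position + config.alpha * r * (mean - state.positions)
    return _clip(cand)


def search_space(
    state: SwarmState,
    config: BESConfig,
    rng: np.random.Generator | None = None,
    *,
    x: np.ndarray | None = None,
    y: np.ndarray | None = None,
) -> np.ndarray:
    """Search-space candidates: local exploration around each agent.

    Agent i pairs with agent i+1 (the last wraps to the first).  x and y are
    one U[-1,1] scalar per agent.
    """
    n = state.positions.shape[0]
    if x is None:
        x = rng.uniform(-1.0, 1.0, size=n)
    if y is None:
        y = rng.uniform(-1.0, 1.0, size=n)
    x = np.asarray(x, dtype=float).reshape(n, 1)
    y = np.asarray(y, dtype=float).reshape(n, 1)
    pos = state.positions
    nxt = np.roll(pos, -1, axis=0)
    mean = state.mean_position
    cand = pos + y * (pos - nxt) + x * (pos - mean)
    return _clip(cand)


def swoop(
    state: SwarmState,
    config: BESConfig,
    rng: np.random.Generator | None = None,
    *,
    rand: np.ndarray | None = None,
    x1: np.ndarray | None = None,
    y1: np.ndarray | None = None,
) -> np.ndarray:
    """Swoop candidates: dive toward the best solution found so far."""
    n = state.positions.shape[0]
    if rand is None:
        rand = rng.random(n)
    if x1 is None:
        x1 = rng.uniform(-1.0, 1.0, size=n)
    if y1 is None:
        y1 = rng.uniform(-1.0, 1.0, size=n)
    rand = np.asarray(rand, dtype=float).reshape(n, 1)
    x1 = np.asarray(x1, dtype=float).reshape(n, 1)
    y1 = np.asarray(y1, dtype=float).reshape(n, 1)
    pos = state.positions
    mean = state.mean_position
    best = state.best_position
    cand = rand * best + x1 * (pos - config.c1 * mean) + y1 * (pos - config.c2 * best)
    return _clip(cand)


def _evaluate(fitness: Callable[[np.ndarray], float], positions: np.ndarray) -> np.ndarray:
    vals = np.array([float(fitness(p)) for p in positions])
    if not np.isfinite(vals).all():
        bad = positions[~np.isfinite(vals)][0]
        raise ValueError(f"non-finite fitness at position {bad}")
    return vals


def optimize(
    fitness: Callable[[np.ndarray], float],
    D: int,
    config: BESConfig,
) -> tuple[np.ndarray, float, list[float]]:
    """Run BES on [0,1]^D and return (best position, best fitness, history).

    All three phases run every epoch in select → search → swoop order; after
    each phase a candidate replaces its agent only when strictly better.  The
    history records the incumbent best fitness at the end of each epoch
    (length = config.epochs) and is monotone by construction.
    """
    rng = np.random.default_rng(config.seed)
    sign = 1.0 if config.maximize else -1.0

    positions = rng.random((config.population, D))
    fitnesses = _evaluate(fitness, positions)
    best_idx = int(np.argmax(sign * fitnesses))
    state = SwarmState(
        positions=positions,
        fitnesses=fitnesses,
        best_position=positions[best_idx].copy(),
        best_fitness=float(fitnesses[best_idx]),
    )

    for epoch in range(config.epochs):
        for phase in (select_space, search_space, swoop):
            candidates = phase(state, config, rng)
            cand_fit = _evaluate(fitness, candidates)
            better = sign * cand_fit > sign * state.fitnesses
            state.positions[better] = candidates[better]
            state.fitnesses[better] = cand_fit[better]
            best_idx = int(np.argmax(sign * state.fitnesses))
            if sign * state.fitnesses[best_idx] > sign * state.best_fitness:
                state.best_fitness = float(state.fitnesses[best_idx])
                state.best_position = state.positions[best_idx].copy()
        state.epoch = epoch + 1
        state.history.append(state.best_fitness)

    return state.best_position, state.best_fitness, state.history


def history_to_csv(history: list[float], path: str | Path) -> None:
    """Write the best-fitness-per-epoch curve as a two-column CSV."""
    lines = ["epoch,best_fitness"]
    lines += [f"{i + 1},{v!r}" for i, v in enumerate(history)]
    Path(path).write_text("\n".join(lines) + "\n")
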