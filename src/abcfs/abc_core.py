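"""Artificial bee colony (ABC) optimizer over a box-bounded continuous space.

The colony holds SN food sources (candidate solutions); each optimization
cycle runs three phases:

* employed phase — every food source proposes a one-coordinate neighbor
  move ``v_ij = z_ij + phi * (z_ij - z_kj)`` against a random partner k and
  keeps the candidate under greedy (equal-or-better) selection;
* onlooker phase — SN roulette-wheel draws proportional to fitness
  ``1 / (1 + cost)`` each trigger the same move/greedy step on the drawn
  source;
* scout phase — at most one source whose trial counter exceeded ``limit``
  is re-seeded uniformly inside the box.

The population loop is vectorized: each cycle draws all random indices and
step sizes for a phase in bulk and evaluates all candidate positions with
one batched cost call.  Onlooker candidates are built from the positions as
they stand at the start of the phase and acceptances are applied in draw
order; this matches the sequential formulation except when one source is
drawn twice in a single phase.  The same engine evolves R independent
populations in parallel (used by the feature-selection scorer); ``run_abc``
is the R = 1 case.

Randomness comes from a single ``numpy.random.Generator`` seeded from the
config; the draw order per cycle is fixed (employed dims, partners, steps;
onlooker roulette, dims, partners, steps; scout replacement), so runs are
bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "SearchSpace",
    "FoodSource",
    "AbcConfig",
    "AbcResult",
    "init_food",
    "fitness_of",
    "selection_probabilities",
    "neighbor_move",
    "greedy_replace",
    "run_abc",
]


@dataclass(frozen=True)
class SearchSpace:
    """Axis-aligned box: per-dimension lower and upper bounds."""

    lower_bounds: np.ndarray
    upper_bounds: np.ndarray

    def __post_init__(self) -> None:
        lo = np.atleast_1d(np.asarray(self.lower_bounds, dtype=float))
        hi = np.atleast_1d(np.asarray(self.upper_bounds, dtype=float))
        if lo.ndim != 1 or hi.ndim != 1 or lo.shape != hi.shape:
            raise ValueError("bounds must be 1-D vectors of equal length")
        if lo.size == 0:
            raise ValueError("search space must have at least one dimension")
        if np.any(lo > hi):
            raise ValueError("lower_bounds must be <= upper_bounds elementwise")
        object.__setattr__(self, "lower_bounds", lo)
        object.__setattr__(self, "upper_bounds", hi)

    @property
    def dimension(self) -> int:
        return int(self.lower_bounds.size)


@dataclass
class FoodSource:
    """A candidate solution: position, its cost, nectar fitness, and the
    count of consecutive failed improvement attempts."""

    position: np.ndarray
    cost: float = math.nan
    fitness: float = math.nan
    trials: int = 0

    def __post_init__(self) -> None:
        self.position = np.atleast_1d(np.asarray(self.position, dtype=float))


@dataclass(frozen=True)
class AbcConfig:
    """Colony control parameters.

    ``colony_size`` counts employed + onlooker bees; the number of food
    sources SN is half of it.  Defaults (20 / 300 / 200) are the standard
    settings used throughout this package.
    """

    colony_size: int = 20
    max_cycles: int = 300
    limit: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.colony_size <= 0 or self.colony_size % 2:
            raise ValueError("colony_size must be a positive even integer")
        if self.colony_size < 4:
            raise ValueError("colony_size must be >= 4 (partner moves need SN >= 2)")
        if self.max_cycles < 0:
            raise ValueError("max_cycles must be >= 0")
        if self.limit < 0:
            raise ValueError("limit must be >= 0")

    @property
    def n_foods(self) -> int:
        """SN: food sources == employed bees == onlooker bees."""
        return self.colony_size // 2

    def with_seed(self, seed: int) -> "AbcConfig":
        return replace(self, seed=int(seed))


@dataclass
class AbcResult:
    best_position: np.ndarray
    best_cost: float
    final_foods: list
    cost_history: np.ndarray
    scout_count: int = 0


def fitness_of(cost):
    """Nectar fitness ``1 / (1 + cost)`` of a nonnegative cost.

    Accepts scalars or arrays; raises on any negative cost.
    """
    c = np.asarray(cost, dtype=float)
    if np.any(c < 0):
        raise ValueError("cost must be nonnegative")
    out = 1.0 / (1.0 + c)
    return float(out) if np.isscalar(cost) or c.ndim == 0 else out


def selection_probabilities(foods: Sequence[FoodSource]) -> np.ndarray:
    """Roulette probabilities ``p_i = fit_i / sum(fit)`` over the colony."""
    if len(foods) == 0:
        raise ValueError("need at least one food source")
    fit = np.array([f.fitness for f in foods], dtype=float)
    if np.any(~np.isfinite(fit)) or np.any(fit <= 0):
        raise ValueError("all food sources must carry positive finite fitness")
    return fit / fit.sum()


def init_food(
    space: SearchSpace,
    rng: np.random.Generator,
    cost_fn: Callable[[np.ndarray], float] | None = None,
) -> FoodSource:
    """Scout initialization: uniform position inside the box.

    ``position[j] = lo_j + u * (hi_j - lo_j)`` with u ~ U[0, 1) per
    dimension.  Cost and fitness are evaluated when ``cost_fn`` is given,
    else left NaN.
    """
    u = rng.random(space.dimension)
    pos = space.lower_bounds + u * (space.upper_bounds - space.lower_bounds)
    food = FoodSource(position=pos)
    if cost_fn is not None:
        food.cost = float(cost_fn(pos))
        food.fitness = fitness_of(food.cost)
    return food


def neighbor_move(
    foods: Sequence[FoodSource],
    i: int,
    space: SearchSpace,
    rng: np.random.Generator,
) -> np.ndarray:
    """Candidate position for food i from a single-coordinate partner move.

    Picks dimension j and partner k != i uniformly, then
    ``v_ij = z_ij + phi * (z_ij - z_kj)`` with phi ~ U[-1, 1]; the moved
    coordinate is clamped into the box.  ``foods`` is not mutated.
    """
    n = len(foods)
    if n < 2:
        raise ValueError("neighbor_move needs at least 2 food sources")
    if not 0 <= i < n:
        raise IndexError(f"food index {i} out of range")
    j = int(rng.integers(0, space.dimension))
    k = int(rng.integers(0, n - 1))
    if k >= i:
        k += 1
    phi = float(rng.uniform(-1.0, 1.0))
    cand = foods[i].position.copy()
    moved = cand[j] + phi * (cand[j] - foods[k].position[j])
    cand[j] = min(max(moved, space.lower_bounds[j]), space.upper_bounds[j])
    return cand


def greedy_replace(
    food: FoodSource,
    candidate_position: np.ndarray,
    cost_fn: Callable[[np.ndarray], float],
) -> FoodSource:
    """Greedy selection between a food source and a candidate position.

    Equal-or-better nectar (equal-or-lower cost) accepts the candidate and
    resets the trial counter; otherwise the counter is incremented.
    Mutates and returns ``food``.
    """
    cand = np.asarray(candidate_position, dtype=float)
    c = float(cost_fn(cand))
    if c <= food.cost:
        food.position = cand
        food.cost = c
        food.fitness = fitness_of(c)
        food.trials = 0
    else:
        food.trials += 1
    return food


def _roulette(prob: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Vectorized roulette draw: index of the cumulative bin each u falls in.

    prob: (R, SN) rows summing to 1; u: (R, SN) uniforms.  Returns (R, SN)
    integer indices.
    """
    cum = np.cumsum(prob, axis=1)
    draws = (cum[:, None, :] <= u[:, :, None]).sum(axis=2)
    return np.minimum(draws, prob.shape[1] - 1)


def _evolve(
    rng: np.random.Generator,
    lower: np.ndarray,
    upper: np.ndarray,
    eval_fn: Callable[[np.ndarray], np.ndarray],
    n_foods: int,
    max_cycles: int,
    limit: int,
):
    """Evolve R independent colonies in parallel.

    lower/upper: (R, D) per-colony boxes.  eval_fn maps candidate positions
    (R, m, D) to costs (R, m) and must be total and nonnegative on the box.

    Returns (positions, costs, trials, best_pos, best_cost, history,
    scout_counts) with history of shape (max_cycles, R) holding the
    best-so-far cost after each cycle.
    """
    R, D = lower.shape
    span = upper - lower
    rows = np.arange(R)[:, None]
    cols = np.arange(n_foods)[None, :]

    pos = lower[:, None, :] + rng.random((R, n_foods, D)) * span[:, None, :]
    costs = _checked_eval(eval_fn, pos)
    trials = np.zeros((R, n_foods), dtype=np.int64)

    best_i = costs.argmin(axis=1)
    best_cost = costs[rows[:, 0], best_i].copy()
    best_pos = pos[rows[:, 0], best_i].copy()
    history = np.empty((max_cycles, R), dtype=float)
    scout_counts = np.zeros(R, dtype=np.int64)

    def _update_best() -> None:
        i = costs.argmin(axis=1)
        c = costs[rows[:, 0], i]
        better = c < best_cost
        if better.any():
            best_cost[better] = c[better]
            best_pos[better] = pos[better, i[better]]

    def _candidates(src_idx: np.ndarray) -> np.ndarray:
        """One-coordinate partner moves for the sources in src_idx (R, SN)."""
        dims = rng.integers(0, D, size=(R, n_foods))
        partners = rng.integers(0, n_foods - 1, size=(R, n_foods))
        partners = partners + (partners >= src_idx)
        phis = rng.uniform(-1.0, 1.0, size=(R, n_foods))
        cand = pos[rows, src_idx].copy()
        z = cand[rows, cols, dims]
        zk = pos[rows, partners, dims]
        moved = z + phis * (z - zk)
        lo = lower[rows, dims]
        hi = upper[rows, dims]
        cand[rows, cols, dims] = np.minimum(np.maximum(moved, lo), hi)
        return cand

    for cycle in range(max_cycles):
        # employed phase: every source moves once, vectorized greedy accept
        cand = _candidates(np.broadcast_to(cols, (R, n_foods)))
        cand_costs = _checked_eval(eval_fn, cand)
        accept = cand_costs <= costs
        pos[accept] = cand[accept]
        costs[accept] = cand_costs[accept]
        trials[accept] = 0
        trials[~accept] += 1

        # onlooker phase: SN roulette draws on current fitness
        prob = (1.0 / (1.0 + costs))
        prob /= prob.sum(axis=1, keepdims=True)
        draws = _roulette(prob, rng.random((R, n_foods)))
        cand = _candidates(draws)
        cand_costs = _checked_eval(eval_fn, cand)
        # apply in draw order; later draws of a source compare against its
        # already-updated cost
        for t in range(n_foods):
            i = draws[:, t]
            acc = cand_costs[:, t] <= costs[rows[:, 0], i]
            r_acc = np.flatnonzero(acc)
            if r_acc.size:
                pos[r_acc, i[r_acc]] = cand[r_acc, t]
                costs[r_acc, i[r_acc]] = cand_costs[r_acc, t]
                trials[r_acc, i[r_acc]] = 0
            r_rej = np.flatnonzero(~acc)
            trials[r_rej, i[r_rej]] += 1

        _update_best()

        # scout phase: per colony, at most the single most-exhausted source
        scout_u = rng.random((R, D))  # drawn every cycle for a fixed stream
        worst = trials.argmax(axis=1)
        need = trials[rows[:, 0], worst] > limit
        r_sc = np.flatnonzero(need)
        if r_sc.size:
            # eval_fn expects all R colonies: non-scouting colonies submit
            # their current worst food (result discarded)
            scout_pos = pos[rows[:, 0], worst].copy()
            scout_pos[r_sc] = lower[r_sc] + scout_u[r_sc] * span[r_sc]
            scout_costs = _checked_eval(eval_fn, scout_pos[:, None, :])[:, 0]
            new_pos = scout_pos[r_sc]
            new_costs = scout_costs[r_sc]
            pos[r_sc, worst[r_sc]] = new_pos
            costs[r_sc, worst[r_sc]] = new_costs
            trials[r_sc, worst[r_sc]] = 0
            scout_counts[r_sc] += 1
            better = new_costs < best_cost[r_sc]
            if better.any():
                b = r_sc[better]
                best_cost[b] = new_costs[better]
                best_pos[b] = new_pos[better]

        history[cycle] = best_cost

    return pos, costs, trials, best_pos, best_cost, history, scout_counts


def _checked_eval(eval_fn, cand: np.ndarray) -> np.ndarray:
    costs = np.asarray(eval_fn(cand), dtype=float)
    if costs.shape != cand.shape[:2]:
        raise ValueError(
            f"cost function returned shape {costs.shape}, "
            f"expected {cand.shape[:2]}"
        )
    if np.any(costs < 0) or np.any(~np.isfinite(costs)):
        raise ValueError("cost function must be finite and nonnegative on the box")
    return costs


def run_abc(
    cost_fn: Callable,
    space: SearchSpace,
    config: AbcConfig,
    batched: bool = False,
) -> AbcResult:
    """Minimize ``cost_fn`` over the box with the ABC colony.

    Parameters
    ----------
    cost_fn
        Position -> nonnegative cost.  With ``batched=True`` it must map an
        (m, D) matrix of positions to an (m,) cost vector (one call per
        phase instead of one per bee — the hot path for clustering costs).
    space, config
        Search box and colony parameters; ``config.seed`` fixes the run.

    Returns
    -------
    AbcResult
        Best-ever position/cost, the final SN food sources, the per-cycle
        best-cost trajectory (nonincreasing), and the scout-event count.
    """
    if batched:
        def eval_fn(c3d):
            return np.asarray(cost_fn(c3d[0]), dtype=float)[None, :]
    else:
        def eval_fn(c3d):
            return np.array(
                [[float(cost_fn(row)) for row in c3d[0]]], dtype=float
            )

    rng = np.random.default_rng(config.seed)
    lower = space.lower_bounds[None, :]
    upper = space.upper_bounds[None, :]
    pos, costs, trials, best_pos, best_cost, history, scouts = _evolve(
        rng, lower, upper, eval_fn, config.n_foods, config.max_cycles, config.limit
    )
    foods = [
        FoodSource(
            position=pos[0, i].copy(),
            cost=float(costs[0, i]),
            fitness=fitness_of(float(costs[0, i])),
            trials=int(trials[0, i]),
        )
        for i in range(config.n_foods)
    ]
    return AbcResult(
        best_position=best_pos[0],
        best_cost=float(best_cost[0]),
        final_foods=foods,
        cost_history=history[:, 0].copy(),
        scout_count=int(scouts[0]),
    )
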