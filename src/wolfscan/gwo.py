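"""Grey wolf optimization (GWO) for bounded continuous minimization.

GWO is a population metaheuristic in which the three best solutions found so
far — the alpha, beta and delta wolves — steer the remaining (omega) wolves.
Each wolf moves toward a stochastic "encirclement" of each leader,

    V = |S * leader - position|,      candidate = leader - U * V,

with coefficients ``U = 2*p*q1 - p`` and ``S = 2*q2`` where ``q1``, ``q2``
are uniform on [0, 1] and ``p`` decays linearly from 2 to 0 over the run.
The new position is the arithmetic mean of the three per-leader candidates,
projected back into the search box.  Large ``|U|`` (early iterations) favours
exploration; ``|U| < 1`` pulls wolves onto the leaders (exploitation).

Coefficients are drawn independently per wolf, per leader and per dimension;
``p`` is shared across the pack within an iteration.  Fitness is minimized —
maximize by negating the objective.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "SearchSpace",
    "Wolf",
    "Pack",
    "CoefficientDraw",
    "GWOConfig",
    "GWOResult",
    "linear_decay",
    "draw_coefficients",
    "encircle_step",
    "clamp",
    "rank_pack",
    "hunt_update",
    "optimize",
    "OBJECTIVES",
]


class ScheduleError(ValueError):
    """Invalid decay schedule (t out of range or t_max < 1)."""


class DimensionError(ValueError):
    """Vector lengths do not agree with the search space."""


class ObjectiveError(ValueError):
    """The objective returned a non-finite value."""

    def __init__(self, position: np.ndarray, value: float):
        self.position = np.asarray(position)
        self.value = value
        super().__init__(
            f"objective returned non-finite value {value!r} at position "
            f"{self.position.tolist()}"
        )


@dataclass(frozen=True)
class SearchSpace:
    """Axis-aligned box of feasible positions."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        if lower.ndim != 1 or upper.shape != lower.shape:
            raise DimensionError("lower and upper must be 1-D and equal length")
        if not np.all(lower < upper):
            raise ValueError("every lower bound must be strictly below its upper bound")
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)

    @property
    def n_dims(self) -> int:
        return self.lower.shape[0]


@dataclass
class Wolf:
    """A candidate solution: a position in the box and its objective value."""

    position: np.ndarray
    fitness: float = np.inf


@dataclass
class Pack:
    """The population plus its leadership hierarchy.

    ``alpha``, ``beta``, ``delta`` are the three distinct lowest-fitness
    wolves (ties broken by lower wolf index); all others are omegas.
    """

    wolves: list[Wolf]
    alpha: Wolf | None = None
    beta: Wolf | None = None
    delta: Wolf | None = None
    iteration: int = 0


@dataclass(frozen=True)
class CoefficientDraw:
    """One stochastic coefficient draw for a single encirclement."""

    p: float
    q1: np.ndarray
    q2: np.ndarray
    U: np.ndarray
    S: np.ndarray


@dataclass(frozen=True)
class GWOConfig:
    n_wolves: int = 8
    n_iterations: int = 50
    seed: int = 0
    tolerance: float | None = None  # optional early-stop fitness threshold

    def __post_init__(self):
        if self.n_wolves < 3:
            raise ValueError("GWO needs at least 3 wolves (alpha, beta, delta)")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be positive")


@dataclass
class GWOResult:
    best_position: np.ndarray
    best_fitness: float
    history: list[dict] = field(default_factory=list)
    config: GWOConfig | None = None

    def to_json(self) -> str:
        payload = {
            "best_position": np.asarray(self.best_position).tolist(),
            "best_fitness": float(self.best_fitness),
            "history": [
                {
                    "iteration": h["iteration"],
                    "best_fitness": float(h["best_fitness"]),
                    "alpha": np.asarray(h["alpha"]).tolist(),
                    "beta": np.asarray(h["beta"]).tolist(),
                    "delta": np.asarray(h["delta"]).tolist(),
                }
                for h in self.history
            ],
            "config": None
            if self.config is None
            else {
                "n_wolves": self.config.n_wolves,
                "n_iterations": self.config.n_iterations,
                "seed": self.config.seed,
                "tolerance": self.config.tolerance,
            },
        }
        return json.dumps(payload, indent=2)


def linear_decay(t: int, t_max: int) -> float:
    """Decay coefficient p, linear from 2 at t=0 down to 0 at t=t_max."""
    if t_max < 1:
        raise ScheduleError("t_max must be >= 1")
    if not 0 <= t <= t_max:
        raise ScheduleError(f"iteration {t} outside [0, {t_max}]")
    return 2.0 * (1.0 - t / t_max)


def draw_coefficients(p: float, rng: np.random.Generator, n_dims: int = 1) -> CoefficientDraw:
    """Draw per-dimension U and S for one wolf/leader encirclement."""
    q1 = rng.uniform(0.0, 1.0, size=n_dims)
    q2 = rng.uniform(0.0, 1.0, size=n_dims)
    return CoefficientDraw(p=p, q1=q1, q2=q2, U=2.0 * p * q1 - p, S=2.0 * q2)


def encircle_step(
    position: np.ndarray, leader: np.ndarray, U: np.ndarray | float, S: np.ndarray | float
) -> np.ndarray:
    """Candidate position from encircling one leader.

    Componentwise ``V = |S*leader - position|`` then ``leader - U*V``.
    """
    position = np.asarray(position, dtype=float)
    leader = np.asarray(leader, dtype=float)
    if position.shape != leader.shape:
        raise DimensionError(
            f"position shape {position.shape} != leader shape {leader.shape}"
        )
    V = np.abs(S * leader - position)
    return leader - U * V


def clamp(position: np.ndarray, space: SearchSpace) -> np.ndarray:
    """Project a position onto the search box, coordinate by coordinate."""
    position = np.asarray(position, dtype=float)
    if position.shape != space.lower.shape:
        raise DimensionError(
            f"position length {position.shape} != space dims {space.n_dims}"
        )
    return np.clip(position, space.lower, space.upper)


def rank_pack(pack: Pack) -> Pack:
    """Assign alpha/beta/delta as the three lowest-fitness wolves.

    Ties break toward the lower wolf index so ranking is reproducible.
    """
    if len(pack.wolves) < 3:
        raise ValueError("a pack needs at least 3 wolves to rank")
    order = sorted(range(len(pack.wolves)), key=lambda i: (pack.wolves[i].fitness, i))
    pack.alpha = pack.wolves[order[0]]
    pack.beta = pack.wolves[order[1]]
    pack.delta = pack.wolves[order[2]]
    return pack


def hunt_update(wolf: Wolf, pack: Pack, p: float, rng: np.random.Generator) -> np.ndarray:
    """One position update: mean of the three per-leader candidates.

    Coefficient draws are independent per leader and per dimension; the draw
    order is alpha, beta, delta with (q1 vector, q2 vector) per leader.
    """
    if pack.alpha is None or pack.beta is None or pack.delta is None:
        raise ValueError("pack has no ranked leaders; call rank_pack first")
    n = wolf.position.shape[0]
    candidates = []
    for leader in (pack.alpha, pack.beta, pack.delta):
        draw = draw_coefficients(p, rng, n_dims=n)
        candidates.append(encircle_step(wolf.position, leader.position, draw.U, draw.S))
    return (candidates[0] + candidates[1] + candidates[2]) / 3.0


def _evaluate(objective: Callable[[np.ndarray], float], position: np.ndarray) -> float:
    value = float(objective(position))
    if not np.isfinite(value):
        raise ObjectiveError(position, value)
    return value


def optimize(
    objective: Callable[[np.ndarray], float],
    space: SearchSpace,
    config: GWOConfig,
) -> GWOResult:
    """Run GWO on ``objective`` over ``space``.

    The pack is initialized uniformly in the box; each iteration updates the
    shared decay ``p``, ranks the pack, moves every wolf via `hunt_update`,
    clamps to bounds and re-evaluates.  The returned optimum is the best
    position ever evaluated (tracked separately from the current alpha, so it
    never regresses).  Identical seed and config give identical results.
    """
    rng = np.random.default_rng(config.seed)
    n = space.n_dims
    positions = rng.uniform(space.lower, space.upper, size=(config.n_wolves, n))
    pack = Pack(wolves=[Wolf(position=positions[i].copy()) for i in range(config.n_wolves)])
    for w in pack.wolves:
        w.fitness = _evaluate(objective, w.position)

    best_idx = min(range(config.n_wolves), key=lambda i: (pack.wolves[i].fitness, i))
    best_position = pack.wolves[best_idx].position.copy()
    best_fitness = pack.wolves[best_idx].fitness

    history: list[dict] = []
    rank_pack(pack)
    history.append(
        {
            "iteration": 0,
            "best_fitness": best_fitness,
            "alpha": pack.alpha.position.copy(),
            "beta": pack.beta.position.copy(),
            "delta": pack.delta.position.copy(),
        }
    )

    for t in range(1, config.n_iterations + 1):
        p = linear_decay(t - 1, config.n_iterations)
        rank_pack(pack)
        # Leaders' positions are snapshotted so every wolf in the iteration
        # moves against the same hierarchy.
        snapshot = Pack(
            wolves=pack.wolves,
            alpha=Wolf(pack.alpha.position.copy(), pack.alpha.fitness),
            beta=Wolf(pack.beta.position.copy(), pack.beta.fitness),
            delta=Wolf(pack.delta.position.copy(), pack.delta.fitness),
        )
        for wolf in pack.wolves:
            new_pos = clamp(hunt_update(wolf, snapshot, p, rng), space)
            wolf.position = new_pos
            wolf.fitness = _evaluate(objective, new_pos)
            if wolf.fitness < best_fitness:
                best_fitness = wolf.fitness
                best_position = wolf.position.copy()
        rank_pack(pack)
        pack.iteration = t
        history.append(
            {
                "iteration": t,
                "best_fitness": best_fitness,
                "alpha": pack.alpha.position.copy(),
                "beta": pack.beta.position.copy(),
                "delta": pack.delta.position.copy(),
            }
        )
        if config.tolerance is not None and best_fitness <= config.tolerance:
            break

    return GWOResult(
        best_position=best_position,
        best_fitness=best_fitness,
        history=history,
        config=config,
    )


def sphere(x: np.ndarray) -> float:
    return float(np.sum(np.square(x)))


def abs_shift(x: np.ndarray, c: float = 1.0) -> float:
    return float(np.sum(np.abs(np.asarray(x) - c)))


def rastrigin(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(10.0 * x.size + np.sum(x * x - 10.0 * np.cos(2 * np.pi * x)))


#: Benchmark objectives by name, for the CLI benchmark runner.
OBJECTIVES: dict[str, Callable[[np.ndarray], float]] = {
    "sphere": sphere,
    "abs": abs_shift,
    "rastrigin": rastrigin,
}
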