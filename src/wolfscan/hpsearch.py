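"""GWO-driven hyperparameter search for a training callback.

The search moves in a continuous box; integer dimensions (batch size, dense
units, epochs) are rounded only when a position is decoded into a concrete
assignment, so the optimizer's dynamics stay purely continuous.  Fitness is
``1 - validation accuracy`` (minimized), with ties between assignments
broken by lower validation loss when the best is selected.  A cache keyed
by the decoded assignment ensures a trainer is never run twice on the same
hyperparameters.

The default search space follows the published tuning ranges:
learning_rate in [0.001, 0.01], batch_size in [32, 128], momentum in
[0.9, 0.99], dense_units in [128, 512], epochs in [10, 50].  dense_units
controls the first head layer; the second is fixed at half of it.  Because
training uses the Adam optimizer, the momentum dimension maps to Adam's
first-moment decay (beta_1) when >= 0.9 and is otherwise ignored; the
mapping is recorded in the evaluation log.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .gwo import DimensionError, GWOConfig, GWOResult, SearchSpace, optimize

__all__ = [
    "HyperParamSpace",
    "HyperParams",
    "FitnessCache",
    "decode_position",
    "fitness_of",
    "search",
    "random_search",
    "table_ranges",
]


@dataclass(frozen=True)
class _Dim:
    name: str
    kind: str  # "continuous" | "integer"
    lower: float
    upper: float

    def __post_init__(self):
        if self.kind not in ("continuous", "integer"):
            raise ValueError(f"kind must be continuous or integer, got {self.kind!r}")
        if not self.lower <= self.upper:
            raise ValueError(f"{self.name}: lower must be <= upper")
        if self.kind == "integer" and not (
            float(self.lower).is_integer() and float(self.upper).is_integer()
        ):
            raise ValueError(f"{self.name}: integer dimension needs integer bounds")


def table_ranges() -> list[tuple[str, str, float, float]]:
    """The default tuning ranges for all five models."""
    return [
        ("learning_rate", "continuous", 0.001, 0.01),
        ("batch_size", "integer", 32, 128),
        ("momentum", "continuous", 0.9, 0.99),
        ("dense_units", "integer", 128, 512),
        ("epochs", "integer", 10, 50),
    ]


@dataclass(frozen=True)
class HyperParamSpace:
    dims: tuple[_Dim, ...] = ()

    def __post_init__(self):
        dims = tuple(
            d if isinstance(d, _Dim) else _Dim(*d) for d in (self.dims or ())
        )
        if not dims:
            dims = tuple(_Dim(*d) for d in table_ranges())
        names = [d.name for d in dims]
        if len(set(names)) != len(names):
            raise ValueError("dimension names must be unique")
        object.__setattr__(self, "dims", dims)

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.dims]

    def to_search_space(self) -> SearchSpace:
        lower = np.array([d.lower for d in self.dims], dtype=float)
        upper = np.array([d.upper for d in self.dims], dtype=float)
        # pinned dims (lower == upper) get a sliver of width so the optimizer
        # box stays valid; decode clamps any position back onto the pin
        pinned = upper <= lower
        upper = np.where(pinned, lower + np.maximum(1e-9, np.abs(lower) * 1e-9), upper)
        return SearchSpace(lower=lower, upper=upper)


@dataclass(frozen=True)
class HyperParams:
    """A decoded assignment: integer dims integral, all values in bounds."""

    values: dict

    def key(self) -> tuple:
        return tuple(sorted(self.values.items()))

    def __getitem__(self, name):
        return self.values[name]


class FitnessCache:
    """Memo of decoded assignment -> (fitness, loss, accuracy).

    ``hits``/``misses`` count `fitness_of` queries, so a hit means a
    trainer call was skipped.
    """

    def __init__(self):
        self._store: dict[tuple, tuple] = {}
        self.hits = 0
        self.misses = 0

    def get(self, hp: HyperParams):
        return self._store.get(hp.key())

    def put(self, hp: HyperParams, record: tuple):
        self._store[hp.key()] = record

    def __len__(self):
        return len(self._store)


def decode_position(position: Sequence[float], space: HyperParamSpace) -> HyperParams:
    """Map a continuous position to a concrete assignment.

    Continuous dims pass through; integer dims round half-up to the nearest
    integer then clamp to bounds.  Decoding a decoded assignment is a
    no-op (idempotent).
    """
    position = np.asarray(position, dtype=float)
    if position.shape != (len(space.dims),):
        raise DimensionError(
            f"position length {position.shape} != {len(space.dims)} dims"
        )
    values = {}
    for x, dim in zip(position, space.dims):
        if dim.kind == "integer":
            v = int(math.floor(x + 0.5))
            v = int(min(max(v, dim.lower), dim.upper))
            values[dim.name] = v
        else:
            values[dim.name] = float(min(max(x, dim.lower), dim.upper))
    return HyperParams(values=values)


def fitness_of(
    hp: HyperParams,
    trainer: Callable,
    data: tuple,
    cache: FitnessCache,
    seed: int = 0,
) -> float:
    """1 - validation accuracy for one assignment, memoized by assignment.

    ``trainer(hp, train, validation, seed)`` must return a mapping with
    "loss" and "accuracy" measured on the validation set and be
    deterministic given identical seed and inputs.
    """
    hit = cache.get(hp)
    if hit is not None:
        cache.hits += 1
        return hit[0]
    cache.misses += 1
    train, validation = data
    try:
        record = trainer(hp, train, validation, seed)
    except Exception as exc:
        raise RuntimeError(f"trainer failed for {hp.values}: {exc}") from exc
    fitness = 1.0 - float(record["accuracy"])
    cache.put(hp, (fitness, float(record["loss"]), float(record["accuracy"])))
    return fitness


def search(
    trainer: Callable,
    space: HyperParamSpace,
    gwo_config: GWOConfig,
    data: tuple,
    trainer_seed: int = 0,
) -> tuple[HyperParams, GWOResult, pd.DataFrame]:
    """Optimize the trainer's validation accuracy over the space with GWO.

    Returns the best decoded assignment (lowest fitness, ties broken by
    lower validation loss then first evaluation), the raw GWO result, and
    an evaluation log with one row per objective query (``cache_hit``
    distinguishes true trainer calls).
    """
    if not space.dims:
        raise ValueError("empty hyperparameter space")
    cache = FitnessCache()
    log_rows: list[dict] = []

    def objective(position: np.ndarray) -> float:
        hp = decode_position(position, space)
        was_known = cache.get(hp) is not None
        fitness = fitness_of(hp, trainer, data, cache, seed=trainer_seed)
        entry = cache.get(hp)
        log_rows.append(
            {
                **hp.values,
                "fitness": fitness,
                "loss": entry[1],
                "accuracy": entry[2],
                "cache_hit": was_known,
                "momentum_mapping": _momentum_note(hp),
            }
        )
        return fitness

    result = optimize(objective, space.to_search_space(), gwo_config)
    log = pd.DataFrame(log_rows)
    best_row = log.sort_values(
        ["fitness", "loss"], kind="stable"
    ).iloc[0]
    best = HyperParams(values={d.name: best_row[d.name] for d in space.dims})
    # restore native ints lost through the DataFrame round-trip
    best = decode_position(
        [best.values[d.name] for d in space.dims], space
    )
    return best, result, log


def _momentum_note(hp: HyperParams) -> str:
    m = hp.values.get("momentum")
    if m is None:
        return "n/a"
    return f"adam beta_1={m:.4f}" if m >= 0.9 else "ignored (adam, momentum < 0.9)"


def random_search(
    trainer: Callable,
    space: HyperParamSpace,
    n_draws: int,
    seed: int = 0,
    data: tuple = (),
    trainer_seed: int = 0,
) -> tuple[HyperParams, pd.DataFrame]:
    """Uniform random baseline with the same decode and cache semantics."""
    rng = np.random.default_rng(seed)
    box = space.to_search_space()
    cache = FitnessCache()
    rows = []
    for _ in range(n_draws):
        position = rng.uniform(box.lower, box.upper)
        hp = decode_position(position, space)
        fitness = fitness_of(hp, trainer, data, cache, seed=trainer_seed)
        entry = cache.get(hp)
        rows.append({**hp.values, "fitness": fitness, "loss": entry[1], "accuracy": entry[2]})
    log = pd.DataFrame(rows)
    best_row = log.sort_values(["fitness", "loss"], kind="stable").iloc[0]
    best = decode_position([best_row[d.name] for d in space.dims], space)
    return best, log
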