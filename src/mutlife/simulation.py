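"""Run loop: initialization, steady-state termination and per-run summaries.

A run starts from a random soup (default: a 100x100 lattice with exactly
50% of all sites live, borders included) or from any prepared
:class:`~mutlife.engine.LatticeState`, and repeatedly applies the engine
step until the population reaches a steady state or a maximum number of
generations (default 10,000) has elapsed.

Two steady-state detectors are available. The default, ``population``,
fires when the live-cell count has been identical over the last
``window + 1`` generations (window default 25); it tolerates the constant
-count period-2 oscillators that dominate settled debris, while the window
guards against transient plateaus during the slow population decline. The
stricter ``state`` detector fires when the occupancy grid itself has been
periodic with period <= ``max_period`` over the last ``window``
generations. Traveling patterns (gliders in flight) never satisfy the
state detector; they eventually annihilate at the dead border.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Callable, Literal, Optional, Sequence

import numpy as np

from .engine import (
    WILDTYPE,
    LatticeState,
    MutationParams,
    round_half_away,
    step,
)

__all__ = [
    "RunConfig",
    "RunResult",
    "detect_steady_state",
    "lattice_means",
    "occupancy_fraction",
    "random_soup",
    "run",
]


@dataclass(frozen=True)
class RunConfig:
    """Simulation setup; the defaults are the model's standard conditions
    (100x100 lattice, 50% random soup, at most 10,000 generations)."""

    size: int = 100
    max_generations: int = 10_000
    init_density: float = 0.5
    seed: int = 0
    steady_detector: Literal["population", "state"] = "population"
    window: int = 25
    max_period: int = 2
    birth_rule: Literal["site", "parental"] = "site"
    genome_update: Literal["synchronous", "raster"] = "synchronous"
    inheritance: Literal["all_births", "mutants_only"] = "all_births"
    snapshot_every: Optional[int] = None

    def __post_init__(self) -> None:
        if self.size < 3:
            raise ValueError("lattice side must be at least 3")
        if self.max_generations < 1:
            raise ValueError("max_generations must be positive")
        if not 0.0 <= self.init_density <= 1.0:
            raise ValueError(f"init_density must be in [0, 1], got {self.init_density}")
        if self.window < 1 or self.max_period < 1:
            raise ValueError("window and max_period must be positive")


@dataclass
class RunResult:
    """Summary of one simulation run.

    ``population_trajectory`` includes generation 0, so its length is
    ``end_generation + 1`` and its last entry equals ``end_population``.
    The mean thresholds are averaged over all sites of the final lattice,
    dead sites contributing their wildtype values.
    """

    population_trajectory: np.ndarray
    end_generation: int
    end_population: int
    terminated_by: Literal["steady_state", "max_generations"]
    mean_lonely: float
    mean_born: float
    mean_crowded: float
    final_state: LatticeState


def random_soup(size: int, density: float, rng: np.random.Generator) -> LatticeState:
    """Random initial configuration with an exact live-cell count.

    Exactly ``round(density * size**2)`` sites are set live, chosen
    uniformly without replacement over the full lattice (borders included);
    all genomes start wildtype. At the defaults (size 100, density 0.5)
    this is exactly 5000 live cells.
    """
    if not 0.0 <= density <= 1.0:
        raise ValueError(f"density must be in [0, 1], got {density}")
    n_sites = size * size
    count = round_half_away(density * n_sites)
    occ = np.zeros(n_sites, dtype=np.uint8)
    if count > 0:
        occ[rng.permutation(n_sites)[:count]] = 1
    state = LatticeState.empty(size)
    state.occupancy = occ.reshape(size, size)
    return state


def detect_steady_state(
    pop_history: Sequence[int],
    detector: Literal["population", "state"] = "population",
    window: int = 25,
    max_period: int = 2,
    state_history: Optional[Sequence[np.ndarray]] = None,
) -> bool:
    """Decide whether the run has settled.

    Returns false until the histories cover more than ``window +
    max_period`` generations (so an initially constant history first fires
    at generation ``window + max_period``). ``population``: true iff the
    live count is identical over the last ``window + 1`` entries.
    ``state``: true iff some period ``p <= max_period`` makes each of the
    last ``window`` occupancy grids equal its ``p``-step predecessor.
    """
    if len(pop_history) <= window + max_period:
        return False
    if detector == "population":
        tail = pop_history[-(window + 1):]
        return all(p == tail[0] for p in tail)
    if detector == "state":
        if state_history is None or len(state_history) < window + max_period:
            return False
        grids = list(state_history)[-(window + max_period):]
        for p in range(1, max_period + 1):
            if all(
                np.array_equal(grids[-j], grids[-j - p]) for j in range(1, window + 1)
            ):
                return True
        return False
    raise ValueError(f"unknown steady-state detector {detector!r}")


def run(
    params: MutationParams,
    config: RunConfig,
    initial: Optional[LatticeState] = None,
    rng: Optional[np.random.Generator] = None,
    on_generation: Optional[Callable[[LatticeState], None]] = None,
) -> RunResult:
    """Execute one simulation run to steady state or the generation cap.

    If ``initial`` is omitted, a random soup at ``config.init_density`` is
    drawn first from the run's generator, so a run is fully reproducible
    from ``config.seed`` alone. ``on_generation`` (if given) is called with
    the state after every step, e.g. for snapshot export.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    state = initial if initial is not None else random_soup(
        config.size, config.init_density, rng
    )
    pops = [state.population]
    keep_states = config.steady_detector == "state"
    state_history: Optional[deque] = (
        deque(maxlen=config.window + config.max_period) if keep_states else None
    )
    if keep_states:
        state_history.append(state.occupancy.copy())

    terminated_by: Literal["steady_state", "max_generations"] = "max_generations"
    while state.generation < config.max_generations:
        state, _ = step(
            state,
            params,
            rng,
            birth_rule=config.birth_rule,
            genome_update=config.genome_update,
            inheritance=config.inheritance,
        )
        pops.append(state.population)
        if keep_states:
            state_history.append(state.occupancy.copy())
        if on_generation is not None:
            on_generation(state)
        if detect_steady_state(
            pops,
            config.steady_detector,
            config.window,
            config.max_period,
            state_history,
        ):
            terminated_by = "steady_state"
            break

    mean_lonely, mean_born, mean_crowded = lattice_means(state)
    return RunResult(
        population_trajectory=np.asarray(pops, dtype=np.int64),
        end_generation=state.generation,
        end_population=state.population,
        terminated_by=terminated_by,
        mean_lonely=mean_lonely,
        mean_born=mean_born,
        mean_crowded=mean_crowded,
        final_state=state,
    )


def lattice_means(state: LatticeState) -> tuple[float, float, float]:
    """Mean of each threshold grid over all sites (dead sites are wildtype)."""
    return (
        float(state.lonely.mean()),
        float(state.born.mean()),
        float(state.crowded.mean()),
    )


def occupancy_fraction(state: LatticeState) -> float:
    """Live-cell count divided by the total number of lattice sites."""
    return state.population / float(state.size * state.size)
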