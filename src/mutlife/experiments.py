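"""Parameter-sweep experiments over mutation rate and magnitude.

The reference sweep varies the mutation rate over
``(0, 0.01, 0.05, 0.1, 0.2, 0.4, 1.0)`` and the mutation magnitude over
``(0.25, 0.5, 0.75, 1.0, 1.5, 2, 3, 4, 5, 6, 10)`` — a 7 x 11 grid — with
the standard run conditions (100x100 lattice, 50% soup, 10,000-generation
cap). Summaries collected per run: the generation and population at
termination, the final occupancy percentage and the lattice-mean values of
the three thresholds.

Derived quantities: the ash density of the unmutated model (~3% of sites),
the maximum occupancy attained under strong mutation (approaching the
analytic packing value ``(5/9 + 5/8) / 2 = 0.5902``), and the critical
mutation magnitude at which dense, tumor-like growth first appears.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .engine import MutationParams
from .simulation import RunConfig, run

__all__ = [
    "REFERENCE_MAGNITUDES",
    "REFERENCE_RATES",
    "SWEEP_COLUMNS",
    "TUMOR_OCCUPANCY_PCT",
    "ash_density",
    "critical_magnitude",
    "derive_seed",
    "max_occupancy",
    "run_sweep",
]

#: Reference grid of mutation rates.
REFERENCE_RATES: tuple[float, ...] = (0.0, 0.01, 0.05, 0.1, 0.2, 0.4, 1.0)

#: Reference grid of mutation magnitudes.
REFERENCE_MAGNITUDES: tuple[float, ...] = (
    0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0, 6.0, 10.0
)

#: Final occupancy (percent of sites) above which a run counts as dense,
#: tumor-like growth: an order of magnitude above the ~2.9% ash density and
#: well below the ~59% packing ceiling.
TUMOR_OCCUPANCY_PCT: float = 20.0

SWEEP_COLUMNS = [
    "rate",
    "magnitude",
    "replicate",
    "seed",
    "end_generation",
    "end_population",
    "occupancy_pct",
    "mean_lonely",
    "mean_born",
    "mean_crowded",
    "terminated_by",
]


def derive_seed(base_seed: int, rate_index: int, mag_index: int, replicate: int) -> int:
    """Deterministic per-cell seed for a sweep run (independent streams)."""
    ss = np.random.SeedSequence(base_seed, spawn_key=(rate_index, mag_index, replicate))
    return int(ss.generate_state(1)[0] % (2**31))


def run_sweep(
    rates: Sequence[float] = REFERENCE_RATES,
    magnitudes: Sequence[float] = REFERENCE_MAGNITUDES,
    replicates: int = 1,
    base_seed: int = 0,
    config: Optional[RunConfig] = None,
) -> pd.DataFrame:
    """One independent run per (rate, magnitude, replicate) grid cell.

    Rows appear in deterministic rate-major order; each run's seed is
    derived from ``(base_seed, rate index, magnitude index, replicate)``,
    so the same arguments always reproduce the same table. ``config``
    supplies the run conditions (its own seed field is ignored).
    """
    if len(rates) == 0 or len(magnitudes) == 0:
        raise ValueError("rate and magnitude grids must be nonempty")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    base = config if config is not None else RunConfig()
    rows = []
    for i, rate in enumerate(rates):
        for j, mag in enumerate(magnitudes):
            for rep in range(replicates):
                seed = derive_seed(base_seed, i, j, rep)
                cfg = RunConfig(
                    size=base.size,
                    max_generations=base.max_generations,
                    init_density=base.init_density,
                    seed=seed,
                    steady_detector=base.steady_detector,
                    window=base.window,
                    max_period=base.max_period,
                    birth_rule=base.birth_rule,
                    genome_update=base.genome_update,
                    inheritance=base.inheritance,
                )
                result = run(MutationParams(rate=rate, magnitude=mag), cfg)
                n_sites = cfg.size * cfg.size
                rows.append(
                    {
                        "rate": rate,
                        "magnitude": mag,
                        "replicate": rep,
                        "seed": seed,
                        "end_generation": result.end_generation,
                        "end_population": result.end_population,
                        "occupancy_pct": 100.0 * result.end_population / n_sites,
                        "mean_lonely": result.mean_lonely,
                        "mean_born": result.mean_born,
                        "mean_crowded": result.mean_crowded,
                        "terminated_by": result.terminated_by,
                    }
                )
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


def ash_density(
    replicates: int = 10,
    base_seed: int = 0,
    config: Optional[RunConfig] = None,
) -> tuple[float, float]:
    """Mean and sample s.d. (percent of sites) of final occupancy without
    mutation, over independent random soups. At the standard conditions the
    settled Conway debris occupies about 2.9 +/- 0.3 percent of the lattice.
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates for a standard deviation")
    table = run_sweep(
        rates=[0.0],
        magnitudes=[0.0],
        replicates=replicates,
        base_seed=base_seed,
        config=config,
    )
    occ = table["occupancy_pct"].to_numpy()
    return float(occ.mean()), float(occ.std(ddof=1))


def max_occupancy(table: pd.DataFrame) -> float:
    """Largest final occupancy percentage over the sweep rows."""
    if len(table) == 0:
        raise ValueError("sweep table is empty")
    return float(table["occupancy_pct"].max())


def critical_magnitude(
    table: pd.DataFrame,
    occupancy_threshold_pct: float = TUMOR_OCCUPANCY_PCT,
) -> Optional[float]:
    """Smallest magnitude in the table at which any run grew densely.

    A magnitude qualifies when at least one of its rows ends with final
    occupancy at or above ``occupancy_threshold_pct``. Returns ``None``
    when no magnitude qualifies.
    """
    if len(table) == 0:
        raise ValueError("sweep table is empty")
    for mag in sorted(table["magnitude"].unique()):
        sub = table[table["magnitude"] == mag]
        if (sub["occupancy_pct"] >= occupancy_threshold_pct).any():
            return float(mag)
    return None
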