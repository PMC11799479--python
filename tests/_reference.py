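"""Naive double-loop reference engine, independent of the vectorized one.

Fate decisions, neighbor counting and parent resolution are re-derived here
with explicit per-cell loops; only the documented per-step randomness
contract (batched draws over births in row-major order) is shared, so that
trajectories are comparable draw for draw.
"""

from __future__ import annotations

import math

import numpy as np

from mutlife.engine import LatticeState

_OFFSETS = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
)

_WT = (2.0, 3.0, 3.0)


def _rha(x: float) -> int:
    """Half-away-from-zero rounding, written independently."""
    if x >= 0:
        return int(math.floor(x + 0.5))
    return -int(math.floor(-x + 0.5))


def naive_step(
    state: LatticeState,
    rate: float,
    magnitude: float,
    rng: np.random.Generator,
    inheritance: str = "all_births",
) -> LatticeState:
    """One synchronous generation via explicit per-cell loops."""
    s = state.size
    occ = state.occupancy
    lon, brn, crw = state.lonely, state.born, state.crowded

    next_occ = np.zeros_like(occ)
    births = []  # row-major by construction
    for r in range(1, s - 1):
        for c in range(1, s - 1):
            n = 0
            for dr, dc in _OFFSETS:
                if occ[r + dr, c + dc]:
                    n += 1
            if occ[r, c]:
                if _rha(lon[r, c]) <= n <= _rha(crw[r, c]):
                    next_occ[r, c] = 1
            elif n == _rha(brn[r, c]):
                next_occ[r, c] = 1
                births.append((r, c))

    next_lon = np.full((s, s), _WT[0])
    next_brn = np.full((s, s), _WT[1])
    next_crw = np.full((s, s), _WT[2])
    survived = (occ == 1) & (next_occ == 1)
    next_lon[survived] = lon[survived]
    next_brn[survived] = brn[survived]
    next_crw[survived] = crw[survived]

    if births:
        parents = []
        ks = []
        for r, c in births:
            live = [
                (r + dr, c + dc) for dr, dc in _OFFSETS if occ[r + dr, c + dc]
            ]
            parents.append(live)
            ks.append(len(live))
        # shared randomness contract: batched draws in row-major birth order
        pidx = rng.integers(0, np.asarray(ks))
        gate = rng.random(len(births))
        mutated = gate < rate
        m = int(mutated.sum())
        gene_idx = rng.integers(0, 3, m)
        deltas = magnitude * rng.standard_normal(m)

        mut_cursor = 0
        for i, (r, c) in enumerate(births):
            pr, pc = parents[i][int(pidx[i])]
            if inheritance == "all_births" or mutated[i]:
                child = [lon[pr, pc], brn[pr, pc], crw[pr, pc]]
            else:
                child = list(_WT)
            if mutated[i]:
                child[int(gene_idx[mut_cursor])] += deltas[mut_cursor]
                mut_cursor += 1
            next_lon[r, c] = child[0]
            next_brn[r, c] = child[1]
            next_crw[r, c] = child[2]

    return LatticeState(
        occupancy=next_occ,
        lonely=next_lon,
        born=next_brn,
        crowded=next_crw,
        generation=state.generation + 1,
    )
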