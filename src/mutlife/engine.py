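"""Synchronous lattice update for a Game of Life with heritable, mutable rules.

The classic Conway rules (B3/S23) are re-expressed as three integer
thresholds — ``lonely`` (minimum live Moore neighbors for survival),
``born`` (neighbor count triggering a birth at an empty site) and
``crowded`` (maximum live neighbors for survival) — and each lattice site
carries its own real-valued copy of the triple. The wildtype genome is
``(2, 3, 3)``. When a new cell is born it inherits the genome of one live
neighbor chosen uniformly at random, and with probability ``rate`` a single
gene, chosen uniformly among the three, receives an additive perturbation
``magnitude * z`` with ``z ~ N(0, 1)``. Thresholds are rounded
half-away-from-zero to the nearest integer at decision time only; the
unrounded accumulators drift freely and are never clamped. When a cell dies
its site is reset to the wildtype genome, so every empty site always reads
``(2, 3, 3)``.

Border sites are never evaluated for birth or death: the next-generation
occupancy buffer starts all-dead and only interior sites are written, so the
border acts as a permanently dead frame (live border cells in an initial
configuration die at the first step).

Randomness contract
-------------------
All stochastic choices of one step are drawn from a single
:class:`numpy.random.Generator` in a fixed order so that a run is a pure
function of ``(initial state, params, seed)``. In the default synchronous
mode, births are enumerated in row-major site order and the step consumes,
in this order: one vectorized ``integers(0, k)`` draw for the parent index
of every birth (``k`` = number of candidate parents), one ``random(B)``
batch for the mutation gates, one ``integers(0, 3, m)`` batch for the
mutated gene choices and one ``standard_normal(m)`` batch for the
perturbations, where ``m`` is the number of mutated births. The raster
compatibility mode draws per birth instead (parent index, gate, gene,
deviate), interleaved with in-place genome writes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, NamedTuple, Optional, Sequence

import numpy as np

__all__ = [
    "GENES",
    "MOORE_OFFSETS",
    "WILDTYPE",
    "BirthEvent",
    "LatticeState",
    "MutationParams",
    "RuleGenome",
    "StepEvents",
    "cell_fate",
    "choose_parent",
    "inherit_and_mutate",
    "live_neighbor_count",
    "round_half_away",
    "step",
]

GeneName = Literal["lonely", "born", "crowded"]

#: Gene labels in the order used for uniform gene selection.
GENES: tuple[GeneName, GeneName, GeneName] = ("lonely", "born", "crowded")

#: Moore-neighborhood offsets in row-major scan order. Parent selection
#: indexes the live neighbors of a birth site in this order.
MOORE_OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
)

_OFF_R = np.array([dr for dr, _ in MOORE_OFFSETS])
_OFF_C = np.array([dc for _, dc in MOORE_OFFSETS])

Site = tuple[int, int]


@dataclass(frozen=True)
class RuleGenome:
    """One site's rule thresholds, as unrounded real accumulators.

    Values may drift below 0 or above 8; saturation is emergent (a crowded
    threshold rounding to >= 8 can never kill by overcrowding, a lonely
    threshold rounding to <= 0 can never kill by isolation).
    """

    lonely: float
    born: float
    crowded: float

    def __post_init__(self) -> None:
        for name in GENES:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"genome value {name}={v!r} is not finite")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.lonely, self.born, self.crowded)

    def with_delta(self, gene: GeneName, delta: float) -> "RuleGenome":
        """Return a copy with ``delta`` added to one gene."""
        return replace(self, **{gene: getattr(self, gene) + delta})


#: The classic Conway thresholds (B3/S23).
WILDTYPE = RuleGenome(2.0, 3.0, 3.0)


@dataclass(frozen=True)
class MutationParams:
    """Mutation rate (per-birth probability) and magnitude (Gaussian scale)."""

    rate: float
    magnitude: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError(f"mutation rate must be in [0, 1], got {self.rate}")
        if not self.magnitude >= 0.0:
            raise ValueError(f"mutation magnitude must be >= 0, got {self.magnitude}")


class BirthEvent(NamedTuple):
    site: Site
    parent_site: Optional[Site]
    mutated: bool
    gene: Optional[GeneName]
    delta: float


@dataclass
class StepEvents:
    """Per-step observability record: every birth (with its inheritance and
    mutation outcome) and every death, in row-major site order."""

    births: list[BirthEvent] = field(default_factory=list)
    deaths: list[Site] = field(default_factory=list)


@dataclass
class LatticeState:
    """Full simulator state: occupancy plus the three threshold grids.

    Invariants (maintained by :func:`step` and the initializers):

    * all four grids share one square shape;
    * every dead site carries exactly the wildtype genome;
    * every border site is dead for generation >= 1.
    """

    occupancy: np.ndarray
    lonely: np.ndarray
    born: np.ndarray
    crowded: np.ndarray
    generation: int = 0

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=np.uint8)
        self.lonely = np.asarray(self.lonely, dtype=np.float64)
        self.born = np.asarray(self.born, dtype=np.float64)
        self.crowded = np.asarray(self.crowded, dtype=np.float64)
        shape = self.occupancy.shape
        if len(shape) != 2 or shape[0] != shape[1]:
            raise ValueError(f"occupancy grid must be square, got shape {shape}")
        if shape[0] < 3:
            raise ValueError("lattice side must be at least 3 (interior nonempty)")
        for name in GENES:
            g = getattr(self, name)
            if g.shape != shape:
                raise ValueError(
                    f"{name} grid shape {g.shape} != occupancy shape {shape}"
                )
        if self.generation < 0:
            raise ValueError("generation must be non-negative")

    @classmethod
    def empty(cls, size: int) -> "LatticeState":
        """All-dead lattice with wildtype genomes everywhere."""
        return cls(
            occupancy=np.zeros((size, size), dtype=np.uint8),
            lonely=np.full((size, size), WILDTYPE.lonely),
            born=np.full((size, size), WILDTYPE.born),
            crowded=np.full((size, size), WILDTYPE.crowded),
            generation=0,
        )

    @property
    def size(self) -> int:
        return self.occupancy.shape[0]

    @property
    def population(self) -> int:
        return int(self.occupancy.sum())

    def genome_at(self, site: Site) -> RuleGenome:
        r, c = site
        return RuleGenome(
            float(self.lonely[r, c]), float(self.born[r, c]), float(self.crowded[r, c])
        )

    def copy(self) -> "LatticeState":
        return LatticeState(
            occupancy=self.occupancy.copy(),
            lonely=self.lonely.copy(),
            born=self.born.copy(),
            crowded=self.crowded.copy(),
            generation=self.generation,
        )


def round_half_away(x: float) -> int:
    """Round to the nearest integer with exact halves going away from zero.

    This matches the rounding convention applied to the threshold
    accumulators before rule enforcement (``2.5 -> 3``, ``-0.5 -> -1``),
    unlike Python's banker's rounding.
    """
    if not math.isfinite(x):
        raise ValueError(f"cannot round non-finite value {x!r}")
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def _round_grid(grid: np.ndarray) -> np.ndarray:
    """Vectorized half-away-from-zero rounding of a threshold grid."""
    return np.copysign(np.floor(np.abs(grid) + 0.5), grid)


def _neighbor_counts(occ: np.ndarray) -> np.ndarray:
    """Live Moore-neighbor counts for every site (zero-padded outside)."""
    s = occ.shape[0]
    p = np.zeros((s + 2, s + 2), dtype=np.int16)
    p[1:-1, 1:-1] = occ
    return (
        p[:-2, :-2] + p[:-2, 1:-1] + p[:-2, 2:]
        + p[1:-1, :-2] + p[1:-1, 2:]
        + p[2:, :-2] + p[2:, 1:-1] + p[2:, 2:]
    )


def live_neighbor_count(state: LatticeState, site: Site) -> int:
    """Number of occupied sites among the 8 Moore neighbors of an interior site."""
    r, c = site
    s = state.size
    if not (0 < r < s - 1 and 0 < c < s - 1):
        raise ValueError(f"site {site} is on the border; border sites are never evaluated")
    occ = state.occupancy
    return int(sum(occ[r + dr, c + dc] for dr, dc in MOORE_OFFSETS))


Fate = Literal["survive", "die", "born", "stay_dead"]


def cell_fate(alive: bool, n: int, genome: RuleGenome) -> Fate:
    """Next-generation fate of one site given its live-neighbor count ``n``.

    Thresholds are rounded half-away-from-zero before comparison. A live
    cell survives iff ``round(lonely) <= n <= round(crowded)``; a dead site
    spawns iff ``n == round(born)``.
    """
    if alive:
        if round_half_away(genome.lonely) <= n <= round_half_away(genome.crowded):
            return "survive"
        return "die"
    if n == round_half_away(genome.born):
        return "born"
    return "stay_dead"


def choose_parent(
    live_neighbor_sites: Sequence[Site], rng: np.random.Generator
) -> Site:
    """Pick the parent of a new cell uniformly among candidate live neighbors."""
    if len(live_neighbor_sites) == 0:
        raise ValueError("cannot choose a parent from an empty candidate list")
    idx = int(rng.integers(0, len(live_neighbor_sites)))
    return tuple(live_neighbor_sites[idx])


def inherit_and_mutate(
    parent: RuleGenome, params: MutationParams, rng: np.random.Generator
) -> tuple[RuleGenome, bool, Optional[GeneName], float]:
    """Copy a parent genome into a child, possibly perturbing one gene.

    With probability ``params.rate`` exactly one gene, chosen uniformly,
    receives ``delta = magnitude * z`` with ``z`` standard normal; otherwise
    the child is an exact copy. Returns ``(child, mutated, gene, delta)``.
    """
    gate = float(rng.random())
    if gate < params.rate:
        gene = GENES[int(rng.integers(0, 3))]
        delta = params.magnitude * float(rng.standard_normal())
        return parent.with_delta(gene, delta), True, gene, delta
    return parent, False, None, 0.0


def _parental_eligibility(
    occ: np.ndarray, n: np.ndarray, born_r: np.ndarray
) -> np.ndarray:
    """Per-offset eligibility grids for the parental birth rule.

    ``elig[j, r, c]`` is true iff the ``j``-th Moore neighbor of ``(r, c)``
    is live and its rounded born threshold equals the live-neighbor count of
    ``(r, c)``.
    """
    s = occ.shape[0]
    occ_p = np.zeros((s + 2, s + 2), dtype=bool)
    occ_p[1:-1, 1:-1] = occ
    born_p = np.zeros((s + 2, s + 2))
    born_p[1:-1, 1:-1] = born_r
    elig = np.empty((8, s, s), dtype=bool)
    for j, (dr, dc) in enumerate(MOORE_OFFSETS):
        shifted_occ = occ_p[1 + dr : s + 1 + dr, 1 + dc : s + 1 + dc]
        shifted_born = born_p[1 + dr : s + 1 + dr, 1 + dc : s + 1 + dc]
        elig[j] = shifted_occ & (shifted_born == n)
    return elig


def step(
    state: LatticeState,
    params: MutationParams,
    rng: np.random.Generator,
    *,
    birth_rule: Literal["site", "parental"] = "site",
    genome_update: Literal["synchronous", "raster"] = "synchronous",
    inheritance: Literal["all_births", "mutants_only"] = "all_births",
    collect_events: bool = False,
) -> tuple[LatticeState, Optional[StepEvents]]:
    """Advance the lattice by one synchronous generation.

    All fates are computed from the pre-step occupancy and genomes. The next
    occupancy buffer starts all-dead and only interior sites are written,
    so border sites are dead from generation 1 on. Birth sites inherit a
    parent genome plus any new mutation; death sites are reset to wildtype.

    ``birth_rule='site'`` (default) consults the genome stored at the empty
    site itself — wildtype by the reset-on-death invariant, so the born gene
    is inert at decision time. ``birth_rule='parental'`` spawns when the
    neighbor count matches the rounded born gene of at least one live
    neighbor, the parent being uniform among those eligible neighbors.

    ``genome_update='raster'`` replays the in-place, row-major genome
    bookkeeping of a nested-loop implementation (deaths reset and births
    write as they are scanned, so a later birth can inherit from a neighbor
    already reset this generation); occupancy remains synchronous.

    ``inheritance`` controls which births copy a parent genome.
    ``'all_births'`` (default): every birth copies a parent genome and the
    mutation gate only decides whether a perturbation is added on top, so
    mutant clones propagate their genome with every offspring.
    ``'mutants_only'``: only a birth whose mutation gate fires selects a
    parent and copies its genome (plus the fresh perturbation); other
    newborns keep the wildtype genome stored at their reset site, a far
    weaker inheritance channel under which clones spread their genome at
    the mutation rate per birth.

    Returns ``(next_state, events)``; ``events`` is ``None`` unless
    ``collect_events`` is true.
    """
    if genome_update not in ("synchronous", "raster"):
        raise ValueError(f"unknown genome_update mode {genome_update!r}")
    occ = state.occupancy != 0
    n = _neighbor_counts(occ)
    lon_r = _round_grid(state.lonely)
    born_r = _round_grid(state.born)
    crow_r = _round_grid(state.crowded)

    survive = occ & (n >= lon_r) & (n <= crow_r)
    elig: Optional[np.ndarray] = None
    if birth_rule == "site":
        birth_ok = (~occ) & (n == born_r)
    elif birth_rule == "parental":
        elig = _parental_eligibility(occ, n, born_r)
        birth_ok = (~occ) & elig.any(axis=0)
    else:
        raise ValueError(f"unknown birth_rule {birth_rule!r}")

    next_occ = survive | birth_ok
    next_occ[0, :] = next_occ[-1, :] = next_occ[:, 0] = next_occ[:, -1] = False
    birth_mask = next_occ & ~occ
    death_mask = occ & ~next_occ

    # Dead sites (including fresh deaths) revert to wildtype; survivors keep
    # their genomes; birth sites are overwritten below.
    next_lon = np.where(next_occ, state.lonely, WILDTYPE.lonely)
    next_born = np.where(next_occ, state.born, WILDTYPE.born)
    next_crow = np.where(next_occ, state.crowded, WILDTYPE.crowded)

    events = StepEvents() if collect_events else None

    bsites = np.argwhere(birth_mask)  # row-major order
    if len(bsites) > 0:
        if genome_update == "synchronous":
            _births_synchronous(
                state, params, rng, bsites, occ, elig, next_lon, next_born, next_crow,
                inheritance, events,
            )
        else:
            _births_raster(
                state, params, rng, bsites, death_mask, occ, elig,
                next_occ, next_lon, next_born, next_crow, inheritance, events,
            )

    if events is not None:
        events.deaths = [tuple(s) for s in np.argwhere(death_mask)]

    next_state = LatticeState(
        occupancy=next_occ.astype(np.uint8),
        lonely=next_lon,
        born=next_born,
        crowded=next_crow,
        generation=state.generation + 1,
    )
    return next_state, events


def _candidate_matrix(
    bsites: np.ndarray, occ: np.ndarray, elig: Optional[np.ndarray]
) -> np.ndarray:
    """B x 8 boolean matrix of candidate parents for each birth site."""
    r, c = bsites[:, 0], bsites[:, 1]
    if elig is not None:
        return elig[:, r, c].T
    return np.stack([occ[r + dr, c + dc] for dr, dc in MOORE_OFFSETS], axis=1)


def _births_synchronous(
    state: LatticeState,
    params: MutationParams,
    rng: np.random.Generator,
    bsites: np.ndarray,
    occ: np.ndarray,
    elig: Optional[np.ndarray],
    next_lon: np.ndarray,
    next_born: np.ndarray,
    next_crow: np.ndarray,
    inheritance: str,
    events: Optional[StepEvents],
) -> None:
    r, c = bsites[:, 0], bsites[:, 1]
    cand = _candidate_matrix(bsites, occ, elig)
    k = cand.sum(axis=1)
    has_parent = k > 0

    # Degenerate no-parent births (reachable only through hand-built states
    # or a born gene rounding to 0): wildtype child, no draws.
    if not has_parent.all():
        np_idx = ~has_parent
        next_lon[r[np_idx], c[np_idx]] = WILDTYPE.lonely
        next_born[r[np_idx], c[np_idx]] = WILDTYPE.born
        next_crow[r[np_idx], c[np_idx]] = WILDTYPE.crowded

    hp = np.flatnonzero(has_parent)
    if len(hp) == 0:
        if events is not None:
            for site in map(tuple, bsites):
                events.births.append(BirthEvent(site, None, False, None, 0.0))
        return

    parent_idx = rng.integers(0, k[hp])
    gate = rng.random(len(hp))
    mutated = gate < params.rate
    m = int(mutated.sum())
    gene_idx = rng.integers(0, 3, m)
    deltas = params.magnitude * rng.standard_normal(m)

    cum = np.cumsum(cand[hp], axis=1)
    off = (cum > parent_idx[:, None]).argmax(axis=1)
    pr = r[hp] + _OFF_R[off]
    pc = c[hp] + _OFF_C[off]

    child = np.stack(
        [state.lonely[pr, pc], state.born[pr, pc], state.crowded[pr, pc]], axis=0
    )
    mi = np.flatnonzero(mutated)
    child[gene_idx, mi] += deltas
    if inheritance == "mutants_only":
        # non-mutated births keep the wildtype genome of their reset site
        for g, wt in enumerate(WILDTYPE.as_tuple()):
            child[g, ~mutated] = wt

    next_lon[r[hp], c[hp]] = child[0]
    next_born[r[hp], c[hp]] = child[1]
    next_crow[r[hp], c[hp]] = child[2]

    if events is not None:
        full_gene: dict[int, GeneName] = {}
        full_delta: dict[int, float] = {}
        for j, gi, d in zip(mi, gene_idx, deltas):
            full_gene[int(j)] = GENES[int(gi)]
            full_delta[int(j)] = float(d)
        hp_pos = {int(h): j for j, h in enumerate(hp)}
        for i, site in enumerate(map(tuple, bsites)):
            if i in hp_pos:
                j = hp_pos[i]
                inherits = inheritance == "all_births" or bool(mutated[j])
                events.births.append(
                    BirthEvent(
                        site,
                        (int(pr[j]), int(pc[j])) if inherits else None,
                        bool(mutated[j]),
                        full_gene.get(j),
                        full_delta.get(j, 0.0),
                    )
                )
            else:
                events.births.append(BirthEvent(site, None, False, None, 0.0))


def _births_raster(
    state: LatticeState,
    params: MutationParams,
    rng: np.random.Generator,
    bsites: np.ndarray,
    death_mask: np.ndarray,
    occ: np.ndarray,
    elig: Optional[np.ndarray],
    next_occ: np.ndarray,
    next_lon: np.ndarray,
    next_born: np.ndarray,
    next_crow: np.ndarray,
    inheritance: str,
    events: Optional[StepEvents],
) -> None:
    """Row-major in-place genome bookkeeping (nested-loop compatibility).

    Deaths reset and births write into working grids as sites are scanned,
    so a birth can inherit an already-reset (wildtype) genome from a
    neighbor that died earlier in the same scan.
    """
    cur = [state.lonely.copy(), state.born.copy(), state.crowded.copy()]
    cand_all = _candidate_matrix(bsites, occ, elig)
    birth_lookup = {tuple(s): i for i, s in enumerate(bsites)}

    changed = np.argwhere(death_mask | (next_occ & ~occ))
    for site in map(tuple, changed):
        r, c = site
        if site not in birth_lookup:  # a death
            for g, wt in enumerate(WILDTYPE.as_tuple()):
                cur[g][r, c] = wt
            continue
        cand = cand_all[birth_lookup[site]]
        k = int(cand.sum())
        if k == 0:
            for g, wt in enumerate(WILDTYPE.as_tuple()):
                cur[g][r, c] = wt
            if events is not None:
                events.births.append(BirthEvent(site, None, False, None, 0.0))
            continue
        idx = int(rng.integers(0, k))
        j = int((np.cumsum(cand) > idx).argmax())
        pr, pc = r + MOORE_OFFSETS[j][0], c + MOORE_OFFSETS[j][1]
        gate = float(rng.random())
        mutated = gate < params.rate
        inherits = inheritance == "all_births" or mutated
        child = (
            [cur[0][pr, pc], cur[1][pr, pc], cur[2][pr, pc]]
            if inherits
            else list(WILDTYPE.as_tuple())
        )
        gene: Optional[GeneName] = None
        delta = 0.0
        if mutated:
            gi = int(rng.integers(0, 3))
            gene = GENES[gi]
            delta = params.magnitude * float(rng.standard_normal())
            child[gi] += delta
        for g in range(3):
            cur[g][r, c] = child[g]
        if events is not None:
            events.births.append(
                BirthEvent(site, (pr, pc) if inherits else None, mutated, gene, delta)
            )

    for g, (grid, wt) in enumerate(
        zip((next_lon, next_born, next_crow), WILDTYPE.as_tuple())
    ):
        grid[:] = np.where(next_occ, cur[g], wt)
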