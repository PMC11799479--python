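import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mutlife import (
    GENES,
    WILDTYPE,
    LatticeState,
    MutationParams,
    RuleGenome,
    cell_fate,
    choose_parent,
    inherit_and_mutate,
    live_neighbor_count,
    round_half_away,
    step,
)
from conftest import state_from_pattern


class TestRounding:
    @pytest.mark.parametrize(
        "x,expected",
        [
            (3.49, 3),
            (2.5, 3),
            (-0.5, -1),
            (3.0, 3),
            (-2.5, -3),
            (0.5, 1),
            (0.0, 0),
            (-3.49, -3),
            (8.5, 9),
        ],
    )
    def test_half_away_convention(self, x, expected):
        assert round_half_away(x) == expected

    @pytest.mark.parametrize("bad", [math.inf, -math.inf, math.nan])
    def test_non_finite_rejected(self, bad):
        with pytest.raises(ValueError):
            round_half_away(bad)

    @given(st.floats(-100, 100))
    @settings(derandomize=True, max_examples=100)
    def test_within_half_of_input(self, x):
        r = round_half_away(x)
        assert abs(r - x) <= 0.5
        assert isinstance(r, int)


class TestNeighborCount:
    def test_empty_lattice(self):
        state = LatticeState.empty(10)
        assert live_neighbor_count(state, (5, 5)) == 0

    def test_full_block_center(self):
        state = LatticeState.empty(10)
        state.occupancy[4:7, 4:7] = 1
        assert live_neighbor_count(state, (5, 5)) == 8

    def test_blinker_middle(self):
        # middle cell of a horizontal 3-cell row sees exactly its 2 flankers
        state = state_from_pattern("blinker", 11)
        row = 5
        assert state.occupancy[row].sum() == 3
        col = int(np.flatnonzero(state.occupancy[row])[1])
        assert live_neighbor_count(state, (row, col)) == 2

    @pytest.mark.parametrize("site", [(0, 5), (9, 5), (5, 0), (5, 9)])
    def test_border_site_rejected(self, site):
        with pytest.raises(ValueError):
            live_neighbor_count(LatticeState.empty(10), site)


class TestCellFate:
    @pytest.mark.parametrize(
        "alive,n,expected",
        [(True, 0, "die"), (True, 1, "die"), (True, 2, "survive"),
         (True, 3, "survive"), (True, 4, "die"), (True, 8, "die"),
         (False, 2, "stay_dead"), (False, 3, "born"), (False, 4, "stay_dead")],
    )
    def test_wildtype_is_conway(self, alive, n, expected):
        assert cell_fate(alive, n, WILDTYPE) == expected

    def test_thresholds_rounded_before_comparison(self):
        assert cell_fate(True, 5, RuleGenome(2, 3, 5.4)) == "survive"
        assert cell_fate(False, 3, RuleGenome(2, 3.6, 3)) == "stay_dead"
        assert cell_fate(False, 4, RuleGenome(2, 3.6, 3)) == "born"

    def test_saturation_is_emergent(self):
        # crowded rounding to >= 8 can never kill by overcrowding
        assert cell_fate(True, 8, RuleGenome(2, 3, 8.2)) == "survive"
        # lonely rounding to <= 0 can never kill by isolation
        assert cell_fate(True, 0, RuleGenome(-0.4, 3, 3)) == "survive"
        # born outside 0..8 makes a site unable to spawn at all
        g = RuleGenome(2, 9.0, 3)
        assert all(cell_fate(False, n, g) == "stay_dead" for n in range(9))


class TestChooseParent:
    def test_singleton(self, rng):
        assert choose_parent([(3, 4)], rng) == (3, 4)

    def test_empty_rejected(self, rng):
        with pytest.raises(ValueError):
            choose_parent([], rng)

    def test_seeded_choice_is_repeatable(self):
        sites = [(1, 1), (2, 2), (3, 3)]
        a = [choose_parent(sites, np.random.default_rng(7)) for _ in range(10)]
        b = [choose_parent(sites, np.random.default_rng(7)) for _ in range(10)]
        assert a == b

    def test_uniform_over_candidates(self, rng):
        sites = [(0, 0), (0, 1), (0, 2)]
        n = 30_000
        counts = {s: 0 for s in sites}
        for _ in range(n):
            counts[choose_parent(sites, rng)] += 1
        se = math.sqrt(n * (1 / 3) * (2 / 3))
        for s in sites:
            assert abs(counts[s] - n / 3) < 3 * se


class TestInheritAndMutate:
    def test_rate_zero_is_exact_copy(self, rng):
        parent = RuleGenome(1.7, 3.2, 5.9)
        for _ in range(50):
            child, mutated, gene, delta = inherit_and_mutate(
                parent, MutationParams(0.0, 4.0), rng
            )
            assert child == parent and not mutated and gene is None and delta == 0.0

    def test_zero_magnitude_mutates_without_effect(self, rng):
        parent = RuleGenome(2, 3, 3)
        child, mutated, gene, delta = inherit_and_mutate(
            parent, MutationParams(1.0, 0.0), rng
        )
        assert mutated and gene in GENES and delta == 0.0 and child == parent

    def test_monte_carlo_distributions(self):
        from scipy import stats

        rng = np.random.default_rng(99)
        params = MutationParams(rate=0.2, magnitude=2.5)
        parent = WILDTYPE
        n = 10_000
        mutated_count = 0
        gene_counts = dict.fromkeys(GENES, 0)
        deltas = []
        for _ in range(n):
            child, mutated, gene, delta = inherit_and_mutate(parent, params, rng)
            if mutated:
                mutated_count += 1
                gene_counts[gene] += 1
                deltas.append(delta)
                assert child.as_tuple() != parent.as_tuple() or delta == 0.0
            else:
                assert child == parent
        se = math.sqrt(n * params.rate * (1 - params.rate))
        assert abs(mutated_count - n * params.rate) < 3 * se
        se_g = math.sqrt(mutated_count * (1 / 3) * (2 / 3))
        for g in GENES:
            assert abs(gene_counts[g] - mutated_count / 3) < 3 * se_g
        # perturbations are zero-mean normal with s.d. = magnitude
        ks = stats.kstest(np.array(deltas) / params.magnitude, "norm")
        assert ks.pvalue > 0.001


def _occupancy_after(state, steps, rate=0.0, magnitude=0.0, seed=0, **kw):
    rng = np.random.default_rng(seed)
    params = MutationParams(rate, magnitude)
    for _ in range(steps):
        state, _ = step(state, params, rng, **kw)
    return state


class TestStepDynamics:
    def test_blinker_oscillates_with_period_2(self):
        s0 = state_from_pattern("blinker", 11)
        s1 = _occupancy_after(s0.copy(), 1)
        s2 = _occupancy_after(s0.copy(), 2)
        assert not np.array_equal(s1.occupancy, s0.occupancy)
        assert np.array_equal(s2.occupancy, s0.occupancy)
        # vertical after one step: the transposed shape
        assert np.array_equal(s1.occupancy, s0.occupancy.T)

    def test_glider_translates_one_diagonal_per_four_steps(self):
        s0 = state_from_pattern("glider", 30, top_left=(5, 5))
        s4 = _occupancy_after(s0.copy(), 4)
        expected = np.zeros_like(s0.occupancy)
        expected[6:, 6:][s0.occupancy[5:-1, 5:-1] == 1] = 1
        assert np.array_equal(s4.occupancy, expected)

    def test_live_border_cells_die_at_first_step(self):
        state = LatticeState.empty(9)
        state.occupancy[:] = 1
        nxt = _occupancy_after(state, 1)
        border = np.ones((9, 9), dtype=bool)
        border[1:-1, 1:-1] = False
        assert nxt.occupancy[border].sum() == 0

    @pytest.mark.parametrize("inheritance", ["all_births", "mutants_only"])
    @pytest.mark.parametrize("birth_rule", ["site", "parental"])
    def test_dead_sites_stay_wildtype(self, inheritance, birth_rule):
        rng = np.random.default_rng(5)
        state = LatticeState.empty(20)
        state.occupancy = (rng.random((20, 20)) < 0.5).astype(np.uint8)
        params = MutationParams(0.4, 2.0)
        for _ in range(15):
            state, _ = step(
                state, params, rng, inheritance=inheritance, birth_rule=birth_rule
            )
            dead = state.occupancy == 0
            assert np.all(state.lonely[dead] == WILDTYPE.lonely)
            assert np.all(state.born[dead] == WILDTYPE.born)
            assert np.all(state.crowded[dead] == WILDTYPE.crowded)

    def test_rate_zero_keeps_all_grids_wildtype(self):
        rng = np.random.default_rng(3)
        state = LatticeState.empty(20)
        state.occupancy = (rng.random((20, 20)) < 0.5).astype(np.uint8)
        state = _occupancy_after(state, 20, rate=0.0, magnitude=1.0, seed=3)
        assert np.all(state.lonely == 2.0)
        assert np.all(state.born == 3.0)
        assert np.all(state.crowded == 3.0)

    @pytest.mark.parametrize("genome_update", ["synchronous", "raster"])
    def test_identical_seed_identical_trajectory(self, genome_update):
        def trajectory(seed):
            rng = np.random.default_rng(seed)
            state = LatticeState.empty(15)
            state.occupancy = (
                np.random.default_rng(1).random((15, 15)) < 0.5
            ).astype(np.uint8)
            out = []
            params = MutationParams(0.3, 1.5)
            for _ in range(20):
                state, ev = step(
                    state, params, rng,
                    genome_update=genome_update, collect_events=True,
                )
                out.append((state.occupancy.copy(), state.crowded.copy(), ev.births))
            return out

        a, b = trajectory(42), trajectory(42)
        for (occ1, crw1, ev1), (occ2, crw2, ev2) in zip(a, b):
            assert np.array_equal(occ1, occ2)
            assert np.array_equal(crw1, crw2)
            assert ev1 == ev2

    def test_events_match_occupancy_changes(self):
        rng = np.random.default_rng(11)
        state = LatticeState.empty(15)
        state.occupancy = (rng.random((15, 15)) < 0.5).astype(np.uint8)
        params = MutationParams(0.5, 1.0)
        for _ in range(10):
            nxt, events = step(state, params, rng, collect_events=True)
            for ev in events.births:
                r, c = ev.site
                assert state.occupancy[r, c] == 0 and nxt.occupancy[r, c] == 1
                if ev.mutated:
                    assert ev.gene in GENES and ev.parent_site is not None
            for r, c in events.deaths:
                assert state.occupancy[r, c] == 1 and nxt.occupancy[r, c] == 0
            born_sites = {ev.site for ev in events.births}
            died_sites = set(events.deaths)
            changed = np.argwhere(state.occupancy != nxt.occupancy)
            assert {tuple(s) for s in changed} == born_sites | died_sites
            state = nxt

    def test_parentless_birth_gets_wildtype_without_draws(self):
        # a hand-built state violating the dead-site invariant: born rounds
        # to 0 so an isolated empty site fires with no live neighbors
        state = LatticeState.empty(7)
        state.born[3, 3] = 0.2
        rng = np.random.default_rng(0)
        before = rng.bit_generator.state
        nxt, events = step(
            state, MutationParams(1.0, 5.0), rng, collect_events=True
        )
        assert nxt.occupancy[3, 3] == 1
        assert nxt.genome_at((3, 3)) == WILDTYPE
        (ev,) = events.births
        assert ev.parent_site is None and not ev.mutated
        assert rng.bit_generator.state == before  # no randomness consumed

    def test_mutants_only_newborns_are_wildtype_without_mutation(self):
        rng = np.random.default_rng(21)
        state = LatticeState.empty(20)
        state.occupancy = (rng.random((20, 20)) < 0.5).astype(np.uint8)
        state.crowded[state.occupancy == 1] = 6.0  # non-wildtype live cells
        nxt, events = step(
            state, MutationParams(0.0, 1.0), rng,
            inheritance="mutants_only", collect_events=True,
        )
        assert len(events.births) > 0
        for ev in events.births:
            assert nxt.genome_at(ev.site) == WILDTYPE


@given(st.integers(0, 2**31 - 1))
@settings(derandomize=True, max_examples=20, deadline=None)
def test_step_agrees_with_per_site_fates(seed):
    """Each site's occupancy transition equals cell_fate on the pre-state."""
    rng = np.random.default_rng(seed)
    state = LatticeState.empty(12)
    state.occupancy = (rng.random((12, 12)) < 0.4).astype(np.uint8)
    state.crowded += rng.normal(0, 1, (12, 12)) * state.occupancy  # live-only drift
    nxt, _ = step(state, MutationParams(0.2, 1.0), rng)
    for r in range(1, 11):
        for c in range(1, 11):
            n = live_neighbor_count(state, (r, c))
            fate = cell_fate(bool(state.occupancy[r, c]), n, state.genome_at((r, c)))
            expected = fate in ("survive", "born")
            assert bool(nxt.occupancy[r, c]) == expected
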