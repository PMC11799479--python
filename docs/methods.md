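# Methods

## Model

The simulator is a synchronous cellular automaton on an `N × N` square
lattice (default `N = 100`) with an 8-neighbor Moore neighborhood. The
state is one binary occupancy grid plus three real-valued threshold grids
(`lonely`, `born`, `crowded`), one triple per site; the wildtype triple
`(2, 3, 3)` is Conway's B3/S23. Each generation, every interior site's
fate is computed from the pre-step occupancy and pre-step genomes:

- live cell: survives iff `round(lonely) ≤ n ≤ round(crowded)`, where `n`
  is its live Moore-neighbor count;
- empty site: spawns iff `n == round(born)` for the genome stored at the
  site (see *Birth-rule variants*).

Rounding is half-away-from-zero and is applied at decision time only; the
stored accumulators are never rounded or clamped. Saturation is emergent:
a crowded value rounding to ≥ 8 can never kill by overcrowding, a lonely
value rounding to ≤ 0 never kills by isolation, and a born value rounding
outside 0..8 makes a site sterile.

Every newborn cell selects a parent uniformly among its live Moore
neighbors. With probability `rate` ∈ [0, 1] the birth is a mutation
event: one gene, chosen uniformly among the three, receives an additive
perturbation `magnitude · z` with `z` standard normal. When a cell dies
its site's genome reverts to wildtype, so dead sites always carry
`(2, 3, 3)` — an invariant checked throughout the test suite.

Border sites are never evaluated for birth or death: the next-generation
occupancy buffer starts all-dead and only interior sites are written.
Initial random soups do populate the full lattice (so the default 50%
soup has exactly 5,000 live cells, borders included); live border cells
die at the first step.

## Tunable parameters

| parameter | units | default | role |
|---|---|---|---|
| `rate` | probability per birth | — | fraction of births that mutate |
| `magnitude` | threshold units (neighbors) | — | scale of the Gaussian perturbation |
| `size` | sites | 100 | lattice side length |
| `init_density` | fraction | 0.5 | live fraction of the random soup (exact count) |
| `max_generations` | generations | 10,000 | hard cap on a run |
| `window` | generations | 25 | steady-state confirmation window |
| `max_period` | generations | 2 | longest oscillation the state detector accepts |

The reference sweep covers rates `(0, .01, .05, .1, .2, .4, 1)` ×
magnitudes `(.25, .5, .75, 1, 1.5, 2, 3, 4, 5, 6, 10)`.

## Termination

The default detector declares steady state when the live-cell count has
been identical over the last `window + 1` generations. Count constancy
tolerates the period-2, constant-population oscillators (blinkers, toads)
that dominate settled ash, while the 25-generation window guards against
transient plateaus during the slow linear population decline. A stricter
`state` detector instead requires the occupancy grid to be periodic with
period ≤ `max_period` over the window; traveling gliders never satisfy it
and eventually wreck on the dead border. Constant-count oscillators with
population that varies within their period (e.g. the pulsar, period 3)
defeat the population detector, so a small fraction of unmutated runs
genuinely runs to the 10,000-generation cap; they are retained as such.

## Design choices at genuinely open points

- **Inheritance scope.** Two readings of "the newborn inherits the parent's
  mutation state" are implemented. Default `all_births`: every newborn
  copies a parent genome and the mutation gate only decides whether a
  perturbation is added. Variant `mutants_only`: only gate-firing births
  copy a parent; other newborns keep the wildtype triple of their reset
  site. The default was chosen because its emergent behavior matches more
  of the model's characteristic outcomes (rapid saturation under strong
  mutation, peak occupancy near the packing value, crowded means in the
  8.5–9.5 range at magnitude 10); the variant produces markedly slower
  clonal expansion (~2,000 generations to saturate at rate 0.05,
  magnitude 6) and a higher dense-growth onset (~0.75). A consequence of
  the default is that sub-threshold perturbations accumulate along
  unbroken inheritance chains, so dense growth already appears at
  magnitude 0.25 with the 20% occupancy criterion.
- **Birth-rule variants.** Default `site`: the born gene consulted for a
  birth is the one stored at the empty site, which by reset-on-death is
  always wildtype — the born gene is then inert at decision time and
  evolves as a neutral hitchhiker, consistent with its observed near-
  wildtype lattice means. Variant `parental`: an empty site spawns when
  `n` equals the rounded born gene of at least one live neighbor, with
  the parent drawn uniformly among those eligible neighbors; a born gene
  then has direct fitness consequences.
- **Genome bookkeeping.** Default fully synchronous (order-independent,
  hence testable against a per-cell oracle). Variant `raster` replays the
  in-place, row-major bookkeeping of a nested-loop implementation: death
  resets and birth writes land in the working grids as sites are scanned,
  so a later birth can inherit an already-reset wildtype genome from a
  neighbor that died the same generation — a directional artifact. In
  both modes the occupancy update itself is synchronous.
- **Degenerate births.** If a birth fires at a site with no live neighbor
  (reachable only through hand-built states whose born gene rounds to 0),
  the child receives the wildtype genome and no randomness is consumed.
- **Exact-count soups.** Initialization places exactly
  `round(density · N²)` live cells (uniformly without replacement) rather
  than sampling per-site Bernoulli, making the default initial population
  of 5,000 deterministic.
- **Dense-growth criterion.** "Tumor-like" growth is operationalized as
  final occupancy ≥ 20% of the lattice — an order of magnitude above the
  ~2.9% ash density and well below the ~59% packing ceiling.

## Randomness and reproducibility

Each run owns a single `numpy.random.Generator` seeded from its config;
the soup (if any) is drawn first, then each step consumes, in row-major
birth order: one vectorized parent-index draw, the mutation-gate batch,
the gene-choice batch and the normal-deviate batch. A run is therefore a
pure function of `(initial state, params, seed)`, and identical seeds
reproduce trajectories, event logs and output files bit-exactly (the
raster mode draws per birth instead, interleaved with its in-place
writes). Sweep cells derive independent seeds from
`SeedSequence(base_seed, spawn_key=(rate_index, magnitude_index,
replicate))`.

## Problem sizes used by the reproduction script

`scripts/acceptance.py` recomputes every headline quantity at the
standard conditions (100×100, 50% soup, 10,000-generation cap): 25
replicates for the unmutated model's settling time and ash density; 5
replicates at rate 0.05 / magnitude 6 for the saturation time; rates
{0.05, 0.1, 0.4} × magnitudes {4, 6, 10} × 2 replicates for peak
occupancy and the magnitude-10 crowded means; rates {0.05, 0.1} ×
magnitudes {0.25–1.5} × 3 replicates for the dense-growth onset; and a
16-cell subset (rates {0.01–0.4} × magnitudes {0.5–6}) for the lonely
drift bound. The full 77-cell reference sweep is available through
`mutlife sweep` (several minutes of computation with replicates).

## What the generator emulates — and what passing tests show

Synthetic inputs are random soups and canonical Life patterns; no
external data exists for this model. The unmutated limit is pinned
exactly against an independent per-cell double-loop oracle and the
canonical dynamics of library patterns (blinker, toad, block, glider,
Gosper gun), and the mutation machinery is verified distributionally
(binomial gate, uniform gene choice, Gaussian perturbations). Passing
tests therefore show the update rule and its statistics are implemented
as specified; they do not validate the model as a description of real
somatic evolution, which it caricatures at the level of "heritable rules
under selection on a lattice".

## Known limitations

- The dense-growth onset and the accumulated threshold drift are
  sensitive to the inheritance scope (see above); the two provided modes
  bracket a plausible range rather than reproducing one canonical value.
- The population detector can fire during long constant-count plateaus
  that are not true steady states, and conversely never fires on
  constant-period oscillators with varying population.
- Square lattice with a dead frame only; no toroidal wrap, no
  asynchronous schedules beyond the raster bookkeeping variant, no
  multi-state cells, migration or environmental fields.
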