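# mutlife

Conway's Game of Life with heritable, mutable rule thresholds — a minimal
lattice model of somatic evolution and tumor-like growth.

## The model

Classic Life (B3/S23) is rewritten as three integer thresholds applied to
the 8-cell Moore neighborhood of each site:

- **lonely** — a live cell with fewer than `lonely` live neighbors dies
  (wildtype 2);
- **crowded** — a live cell with more than `crowded` live neighbors dies
  (wildtype 3);
- **born** — an empty site with exactly `born` live neighbors spawns a new
  cell (wildtype 3).

Here every lattice site carries its own *real-valued* copy of the triple
`(lonely, born, crowded)` — its rule genome. A newborn cell inherits the
genome of one live neighbor chosen uniformly at random; with probability
`rate` (the **mutation rate**) exactly one of its three genes receives an
additive perturbation `magnitude · z`, `z ~ N(0, 1)` (the **mutation
magnitude**). Thresholds are rounded half-away-from-zero to the nearest
integer at decision time only, so a lineage must accumulate at least ±0.5
in a gene before its behavior changes. When a cell dies its site reverts
to the wildtype genome. Border sites are never evaluated, acting as a
permanently dead frame.

With mutation switched off this is exactly Conway's Life: a 50% random
soup on a 100×100 lattice decays to sparse ash (~2.9% occupancy) within
roughly a thousand generations. With mutation on, selection acts on the
heritable rules: lineages whose crowded threshold drifts upward tolerate
dense packing, out-proliferate wildtype cells and — above a critical
mutation magnitude — fill the lattice with a dense, connected, tumor-like
mass at roughly 59–65% occupancy (the analytic packing scale is
`(5/9 + 5/8)/2 ≈ 0.59`). The crowded gene is the driver; the lonely gene
drifts only downward (relaxed survival) and the born gene is a nearly
neutral hitchhiker.

## Worked example

One dense-growth run from the command line:

```
$ mutlife run --rate 0.05 --magnitude 6 --seed 3 --out out
end_generation=209
end_population=6249
```

The run started from 5,000 live cells (50% of the lattice), transitioned
to unregulated growth and reached a static, saturated steady state after
209 generations with 6,249 live cells — 62.5% of the lattice, near the
packing ceiling and far above the ~2.9% ash left by the unmutated rules
(the same seed with `--rate 0` ends at generation 1710 with 289 cells).
`out/` contains `trajectory.csv` (population per generation), the final
occupancy and threshold grids as CSV, and `manifest.yaml` with the full
effective configuration. The same run through the Python API:

```python
from mutlife import MutationParams, RunConfig, run

res = run(MutationParams(rate=0.05, magnitude=6.0), RunConfig(seed=3))
print(res.end_generation, res.end_population)   # 209 6249
print(res.mean_lonely, res.mean_born, res.mean_crowded)
# 1.33 2.90 6.58  (lattice means; wildtype is 2, 3, 3)
```

The final lattice means show the selection signature: crowded driven from
3 up to 6.6, lonely relaxed downward, born barely moved.

Other entry points:

```
mutlife sweep --rates 0,0.05,0.4 --magnitudes 0.5,2,6 --out sweep/
mutlife patterns list
mutlife run --init glider.rle --rate 0 --detector state --size 30
```

`mutlife sweep` runs one simulation per (rate, magnitude) cell — the full
reference grid is 7 rates × 11 magnitudes — and writes a summary CSV with
end generation, end population, occupancy and final mean thresholds per
run. Initial conditions can also be read from standard Life pattern files
(RLE or plaintext `.cells`) or occupancy CSVs.

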