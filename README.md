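# traplinesim

Simulation toolkit for **trapline formation** in central-place foragers:
how a bumblebee-like agent, flying repeated nest-to-nest foraging bouts
between a fixed set of flowers, converges on a short — often the shortest —
circuit, a task equivalent to the travelling salesman problem (TSP).

The package is aimed at behavioural ecologists and movement modellers who
want to re-run, extend or confront with data the iterative-improvement
heuristic of trapline development, together with the route-optimality
oracles and sequence statistics used to evaluate it.

## The model

A model bee holds a table of transition probabilities `P(i -> j)` over all
locations (nest + flowers). Its behaviour rests on six assumptions:

1. every flower is individually recognisable;
2. every ordered pair of locations has a finite transition probability;
3. initial probabilities are inversely proportional to the **squared
   distance** between the locations, row-normalised:
   `P0(i -> j) ∝ 1 / d_ij²`;
4. the bee measures the total (odometric) length `L` of each bout, revisit
   detours included;
5. a bout that fills the crop (visits the required number of distinct
   rewarding flowers) is compared with the shortest such route experienced
   so far, `L_best`;
6. if `L ≤ L_best`, every directed transition used in the bout is
   multiplied by a common **enhancement factor** `f ≥ 1` and the affected
   rows are renormalised. Repeating a short route therefore reinforces it.

Two sampling rules complete the walk: the bee does not head home until its
crop is full, and it never returns immediately to the flower it has just
left (revisits after at least one intervening visit are permitted and
counted). `f` is interpreted as motivation to optimise and grows with
spatial scale: ~1.1 in metre-scale flight rooms, 1.5–4 in the field.

Around the simulator the package provides:

- **arrays** — flower-array geometries (regular polygons, uniform-random
  patches, clustered patch grids, three synthetic flight-cage layouts in
  which proximity and directionality are positively / independently /
  negatively linked), with CSV/JSON persistence;
- **oracle** — exact shortest circuits (Held–Karp, brute-force
  cross-check), best crop-sized subset circuits, the greedy
  nearest-neighbour baseline, and the all-pairs transposition
  (pairwise-switch) improvability test used at 20+ flowers;
- **metrics** — route similarity index (SI ∈ [0, 1]), the standardized
  binomial asymmetry index of directional transition counts, empirical
  rank p-values against simulated null distributions, cohort summaries;
- **search** — the loop-search model for locating a new or missing flower:
  straight out-and-back legs of exponential length, mean cost
  `⟨L⟩ = 2λ·exp(R/λ)`, minimised at `λ* = R`;
- **experiments** — named, seeded, scale-down-able recipes for the
  standard simulation experiments.

## Worked example

```python
from traplinesim import ModelParams, optimal_circuit, regular_polygon, run_cohort

array = regular_polygon(5, 5.0, nest_at="centroid")   # pentagon, 5 m sides
params = ModelParams(enhancement_factor=2.0, n_bouts=65, rng_seed=42)
cohort = run_cohort(array, params, n_bees=100)

print(optimal_circuit(array).length)        # 28.507 m
print(cohort.fraction_optimal_by(65))       # 0.96
print(cohort.fraction_stable_by(65))        # 0.96
print(round(cohort.mean_best_ratio(), 4))   # 1.0065
```

96% of bees fly the exact shortest circuit at least once within one
simulated day (65 bouts) and lock it into a stable trapline (three
consecutive identical optimal bouts); the cohort's best routes average
0.65% above the optimum. The `examples/` directory has one short script
per capability (pentagon traplines, random-array TSP performance,
crop-limited subset selection, route statistics, loop search, array-type
comparison), each printing the numbers it computes and what they mean.

A thin command line mirrors the library:

```bash
traplinesim run --array flowers.csv --factor 2.0 --bouts 65 --bees 100 --seed 1 --out out/
traplinesim oracle --array flowers.csv --subset-size 4
traplinesim search --lam 10 --R 10 --r 0.5 --runs 1000 --seed 1
traplinesim experiment --name random_tsp --scale 0.1 --seed 7 --out out/
```

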