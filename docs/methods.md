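# Methods

## The traplining heuristic

The simulator models a central-place forager developing a trapline — a
repeatable nest-to-nest circuit over a fixed set of replenishing flowers —
by iterative improvement rather than planning. The agent's only memory is
a table of directed transition probabilities over locations (nest and
flowers).

**Initialisation.** `P0(i -> j) ∝ d_ij^(-q)` with exponent `q = 2`
(configurable via `distance_exponent`), row-normalised so each origin's
outgoing probabilities form a categorical distribution. Row normalisation
is the only reading that defines a sampling rule; because renormalisation
is a per-row scalar, a globally normalised table would induce identical
behaviour. Probabilities depend only on the array's *shape*: rescaling
all coordinates leaves the table unchanged, which is why the enhancement
factor, not geometry, carries the effect of spatial scale.

**Bout generation.** A bout starts at the nest and repeatedly samples the
next location from the current row, with two outcomes masked and
resampled (equivalent to renormalising the row without them):

- the **nest** — a foraging bee heads home only once its crop is full;
- the **flower just departed** — no immediate U-turns. Returns to an
  emptied flower after at least one intervening visit remain possible and
  are counted as revisits.

Both rules were adopted after sensitivity analysis: with the nest
samplable mid-bout it becomes the most attractive target from every
flower of a centroid-nested polygon and stability collapses (~10% instead
of ~95% at `f = 2` on the pentagon); without the U-turn ban the
inverse-square prior locks the walk into A↔B ping-pong between close
pairs and 10-flower cohorts plateau ~70% above the optimum. Per-traversal
reinforcement compounding and undirected (symmetric) reinforcement were
also evaluated and rejected: the former degrades optimisation severely,
the latter cannot produce the directional asymmetry that traplines show
(see the asymmetry index below).

When `crop_capacity` distinct rewarding flowers have been visited the
crop is full and the bee flies straight home. A safety cap
(`max_transitions_per_bout`, default `20 × n_flowers`) closes pathological
bouts; capped bouts are flagged incomplete, never enter the route
comparison, and their rate is reported (≈4% at 10 flowers, bout 1).

**Co-located flowers.** A pair of flowers at identical coordinates
proxies a single double-reward flower. Transitions within the pair are
forbidden (zero probability; a zero distance has no inverse-square
weight), and landing on either member collects both members' nectar —
they share one physical point. Without the latter rule the
reward-prioritisation trend below is not reproducible.

**Reinforcement.** A completed (crop-filling) bout whose odometric length
`L` — all segments, revisit detours included — is no longer than the best
such length so far (`L ≤ L_best`; ties reinforce, and the first
qualifying bout always reinforces since `L_best` starts at infinity)
multiplies each *distinct directed* transition it used by `f` once,
regardless of traversal multiplicity, then renormalises the affected
rows. Directionality matters: it is what lets a habitual flight
direction, and hence transition-count asymmetry, emerge.

**Optimality and stability bookkeeping.** A bout is *optimal* when it
fills the crop with no revisit, never passes the nest mid-route, and its
circuit length matches the exact optimum within 1e-9 relative tolerance
(for crop-limited runs, the optimum over all crop-sized subsets). Length
matching treats a circuit and its reversal as equal automatically.
*Stability* is the first of three consecutive identical optimal bouts;
the default index requires the same direction (a trapline has a habitual
direction), and a reversal-merged index is recorded alongside. Route
identity locks in long before direction does at weak factors.

**Randomness.** One root seed; per-bee streams are spawned through
`numpy.random.SeedSequence` so cohorts are reproducible and
order-independent. Experiment runners spawn one child per arrangement and
split it into an array seed and a cohort seed.

## Route oracles

Exact shortest nest-to-nest circuits come from Held–Karp dynamic
programming (practical to ~15 flowers; ties broken to the
lexicographically smallest order, reversal-merged), cross-checked against
an independent brute-force permutation sweep on small instances.
Crop-limited targets minimise over all `C(n, k)` subsets. The greedy
nearest-neighbour tour (ties to the lowest flower index) is the classical
baseline. For 20-flower experiments no exact optimum is attempted;
instead the all-pairs transposition test asks whether exchanging any two
positions of the visit sequence strictly shortens the circuit. A frozen
counter-example in the test suite shows transposition stability does not
certify optimality, which is why the statistic is only an upper-bound
screen.

## Sequence and transition statistics

**Similarity index (adopted convention).** The historical index is cited
in the behavioural literature without a printed formula. Here
`SI(a, b)` = (ordered flower-to-flower transitions shared between the two
sequences, counted with multiplicity) / (the larger of the two sequences'
transition counts). It is symmetric, respects both order and length, and
meets the defining endpoints (0 for, e.g., 123 vs 456; 1 for identical
sequences). For revisit-free sequences SI = 1 pins the sequence exactly;
revisit-heavy Eulerian rearrangements can in principle tie at 1. The
implementation is pluggable for alternative conventions.

**Asymmetry index (adopted convention).** For each unordered flower pair
with `N = n_ij + n_ji ≥ 6` directional transitions, the two-tailed
binomial probability of the observed split under a 1:1 expectation is
`P = min(1, 2·Pr(X ≥ max(n, N−n)))`, `X ~ Bin(N, ½)` (simple doubled
tail, no point-mass adjustment). Pairs below 6 observations are omitted.
The per-pair score is `−ln P` and the standardized index is the mean over
tested pairs, making windows with different pair counts comparable. A
perfectly balanced table scores 0; a fully one-sided pair with `N = 10`
scores `ln 512 ≈ 6.24`, the magnitude range reported for real traplining
bees. The index is invariant under flower relabelling and under flipping
every pair's direction.

**Empirical rank p-values.** Model agreement with an observed bee is
quantified by ranking the observation within a simulated null (1000 runs
by convention): `p` = fraction of null values at least as slow/worse,
ties counting half (mid-p), clamped below at `1/(2·n_runs)` since a rank
statistic cannot certify impossibility. An observation at the
70th-percentile-quickest point of the null yields `p = 0.3`; rejection
below 0.05. Conditional on a single finite null the p-value distribution
carries `O(n_null^-1/2)` wiggles; uniformity holds when pooled over
nulls.

## Loop search

A searching bee flies straight out from the search origin in a uniform
random direction for an exponential distance with mean `λ`, perceiving
the flower if the leg passes within radius `r` of it (closest-approach
test along the leg; the retraced inbound leg cannot see anything new),
and otherwise retraces and tries again. Extreme-value reasoning — the
search ends when the longest leg becomes comparable with the flower
distance `R`, i.e. `n·Pr(ℓ > R) ≈ 1` — gives `n = exp(R/λ)` loops and a
mean path length `⟨L⟩ = 2λ·exp(R/λ)` (every leg counted out and back,
the successful leg truncated at first perception). Differentiating,
`⟨L⟩` is minimal at `λ* = R`: legs as long, on average, as the expected
flower distance. The closed form counts only the leg-length condition;
simulated loop counts additionally carry an angular hit factor `≈ πR/r`
independent of `λ`, so simulations are compared with the closed form for
proportionality and ordering, never bit-exactly. The optimum is robust to
swapping the exponential for a gamma leg-length family (tested within a
factor 2).

## Synthetic flight-cage arrays

The three 10-flower cage geometries ship as hand-authored synthetic
stand-ins (`data/synthetic_array_*.csv`) for published layouts whose
coordinates are not available; they realise the described geometric
characters and carry qualitative weight only:

- *positive* — flowers along an open arc, nest closing the loop: each
  nearest neighbour lies straight ahead and short transitions chain into
  the optimal circuit;
- *independent* — flowers on a triangle outline: still a loop, but
  corners and near-equal chords decouple proximity from useful direction;
- *negative* — a two-row ladder with tight cross-row rungs: the shortest
  transitions cut across the optimal perimeter circuit, so distance-led
  exploration chains them into long zigzags.

Under the model the ever-optimal and stable fractions order
positive > independent > negative with the negative array at zero, at
both cage-like (1.1) and field-like (1.5) factors. Three-in-a-row
stability of a 10-flower route requires `f ≳ 1.5` within 65 bouts in this
implementation, so at `f = 1.1` the ordering is carried by the
ever-optimal fraction.

## Study conditions and problem sizes

Full-scale experiments use 100 random arrangements × 100 bees, 65 bouts
(one foraging day; 130 for two days without overnight memory loss),
enhancement factor 2 for random-array experiments, flowers uniform in a
square patch with the nest at a corner (patch side 25 m; dynamics are
scale-invariant, so only shape matters). The packaged headline
computations (`scripts/acceptance.py`) and the deepest tests run at desk
scale, 30 × 30, the package's standard reduced cohort; stochastic
cohort-level quantities then carry a standard error of roughly 0.01 on
the mean length ratio and ~1 percentage point on cohort fractions.

At those conditions the package computes, for example: 10-flower cohort
mean `L_best/L_min ≈ 1.27` (the nearest-neighbour reference line is
1.25; the greedy tour itself measures ≈ 1.10 on such instances — 1.25 is
its classical large-instance excess); ~100% of best-found 20-flower
routes transposition-improvable after 65 bouts and ≥ 99% after 130
(reference values 98.5% and 96.5%: the model reproduces the statistic's
level, while the two-day decline is smaller here than reported);
and ~32% of crop-limited bees finding the exact best 4-of-8 circuit
(reference bound ≥ 20%).

## Known limitations

- The generator emulates geometry and reward schedule only: no handling
  times, energetics, competition, overnight memory decay, flower
  detectability limits, or continuous flight paths. Passing tests
  therefore say nothing about those aspects of real foraging.
- Exact optima are limited to ~15 flowers (Held–Karp) and subset
  enumeration to 12; larger instances rely on the improvability screen.
- The similarity and asymmetry formulas are documented conventions, not
  recovered originals; both are pluggable.
- The cage arrays are synthetic approximations; only orderings among
  them, never their absolute fractions, are meaningful.
- The closed-form search cost is an order-of-magnitude estimate; only
  proportionality and the location of its optimum are testable.
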