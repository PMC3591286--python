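"""The iterative-improvement traplining heuristic.

A model bee forages over repeated nest-to-nest bouts in a fixed flower
array.  It holds a table of transition probabilities between all pairs of
locations (nest included), initialised inversely proportional to squared
distance and row-normalised.  Each bout it samples moves from that table
until it has filled its crop (visited a required number of distinct
flowers), then returns directly to the nest.  If the completed route is no
longer than the shortest qualifying route experienced so far, the directed
transitions it used are multiplied by a common enhancement factor ``f`` and
the affected rows renormalised.  Repetition of short routes therefore
reinforces them, and a stable trapline can emerge.

Six behavioural assumptions underlie the model: flowers are individually
recognisable; every pair of locations has a finite transition probability;
initial probabilities follow an inverse-square distance law; the bee
measures total route length odometrically; it compares each completed
route against the best so far; and no-longer routes are reinforced by the
common factor ``f``.  The factor is interpreted as motivation to optimise
and grows with spatial scale (near 1.1 in metre-scale flight rooms, 1.5-4
in the field).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .arrays import FlowerArray
from . import oracle as _oracle

__all__ = [
    "ModelParams",
    "TransitionTable",
    "Bout",
    "BeeRun",
    "CohortResult",
    "init_transition_table",
    "simulate_bout",
    "qualifies_for_comparison",
    "reinforce",
    "run_bee",
    "run_cohort",
]

_ROW_SUM_TOL = 1e-9


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the traplining heuristic.

    enhancement_factor
        Common multiplier ``f >= 1`` applied to the transition
        probabilities of a route no longer than the best so far.
    n_bouts
        Number of consecutive foraging bouts (65 is one simulated day).
    distance_exponent
        Exponent of the initial distance law (default 2: inverse-square).
    crop_capacity
        Distinct rewarding flowers needed to fill the crop; ``None`` means
        all flowers in the array.
    reward_priority_boost
        Multiplier applied to the initial nest->flower probability of
        flowers flagged ``high_reward`` on the array (default 1 = off).
    max_transitions_per_bout
        Safety cap; ``None`` defaults to ``20 * n_flowers``.  Capped bouts
        are flagged incomplete and never reinforced.
    rng_seed
        Root seed; per-bee streams are spawned from it deterministically.
    """

    enhancement_factor: float = 2.0
    n_bouts: int = 65
    distance_exponent: float = 2.0
    crop_capacity: int | None = None
    reward_priority_boost: float = 1.0
    max_transitions_per_bout: int | None = None
    rng_seed: int | None = None

    def __post_init__(self):
        if self.enhancement_factor < 1.0:
            raise ValueError("enhancement_factor must be >= 1")
        if self.n_bouts < 0:
            raise ValueError("n_bouts must be non-negative")
        if self.reward_priority_boost <= 0:
            raise ValueError("reward_priority_boost must be positive")

    def resolve(self, array: FlowerArray) -> "ModelParams":
        """Fill array-dependent defaults (crop capacity, bout cap)."""
        n = array.n_flowers
        crop = self.crop_capacity if self.crop_capacity is not None else n
        if not 1 <= crop <= n:
            raise ValueError("crop_capacity must be between 1 and n_flowers")
        cap = self.max_transitions_per_bout
        if cap is None:
            cap = 20 * n
        if cap < n + 2:
            raise ValueError("max_transitions_per_bout must be >= n_flowers + 2")
        return replace(self, crop_capacity=crop, max_transitions_per_bout=cap)


class TransitionTable:
    """Per-origin categorical distributions over successor locations.

    Row ``i`` is the probability vector for the next move from location
    ``i`` (0 = nest, flower ``k`` = ``k + 1``).  Rows sum to one;
    self-transitions and forbidden moves (between co-located flowers) are
    exactly zero.  A cumulative-sum cache keeps per-move sampling O(log n).
    """

    __slots__ = ("probs", "_cum")

    def __init__(self, probs: np.ndarray):
        probs = np.asarray(probs, dtype=float)
        self.probs = probs
        self._cum = np.cumsum(probs, axis=1)
        self.validate()

    def validate(self) -> None:
        p = self.probs
        if (p < 0).any():
            raise ValueError("negative transition probability")
        if np.abs(p.sum(axis=1) - 1.0).max() > _ROW_SUM_TOL:
            raise ValueError("transition-table row does not sum to 1")
        if np.diag(p).any():
            raise ValueError("self-transition probability must be 0")

    @property
    def n_locations(self) -> int:
        return self.probs.shape[0]

    def sample_next(self, origin: int, rng: np.random.Generator) -> int:
        row = self._cum[origin]
        return int(np.searchsorted(row, rng.random() * row[-1], side="right"))

    def multiply(self, transitions, factor: float) -> None:
        """Multiply the given directed ``(i, j)`` entries by ``factor`` and
        renormalise each affected row in place."""
        if factor == 1.0:
            return
        rows = set()
        for i, j in transitions:
            self.probs[i, j] *= factor
            rows.add(i)
        for i in rows:
            self.probs[i] /= self.probs[i].sum()
            self._cum[i] = np.cumsum(self.probs[i])

    def copy(self) -> "TransitionTable":
        return TransitionTable(self.probs.copy())


def init_transition_table(array: FlowerArray, params: ModelParams) -> TransitionTable:
    """Initial table: entries proportional to ``1 / d^exponent`` per origin row.

    The nest is an ordinary node.  Transitions within a co-located flower
    pair are forbidden (probability 0): the pair proxies a single
    double-reward flower, and a zero distance has no inverse-square weight.
    ``reward_priority_boost`` multiplies the nest row's entries for flowers
    flagged high-reward before renormalisation.
    """
    d = array.distances
    n_loc = d.shape[0]
    with np.errstate(divide="ignore"):
        w = 1.0 / d**params.distance_exponent
    np.fill_diagonal(w, 0.0)
    for pair in array.colocated_pairs:
        a, b = sorted(pair)
        w[a + 1, b + 1] = w[b + 1, a + 1] = 0.0
    if not np.isfinite(w).all():
        raise ValueError("zero distance between locations that are not a flagged co-located pair")
    boost = params.reward_priority_boost
    if boost != 1.0:
        for fidx in array.high_reward:
            w[0, fidx + 1] *= boost
    rows = w.sum(axis=1)
    if (rows <= 0).any():
        raise ValueError("a location has no admissible successor")
    return TransitionTable(w / rows[:, None])


@dataclass(frozen=True)
class Bout:
    """One nest-to-nest trip.

    ``visits`` lists location indices (0 = nest) from departure to return;
    it always starts and ends at 0.  ``length`` is the odometric route
    length: the sum of all segment distances, revisit segments included.
    A revisit is a within-bout return to a flower already emptied in that
    bout.
    """

    visits: tuple[int, ...]
    length: float
    distinct_flowers: int
    revisits: int
    complete: bool

    @property
    def flower_sequence(self) -> tuple[int, ...]:
        """Flower indices visited, in order, nest passages dropped."""
        return tuple(v - 1 for v in self.visits if v != 0)

    @property
    def n_flower_visits(self) -> int:
        return len(self.flower_sequence)


def simulate_bout(
    table: TransitionTable,
    array: FlowerArray,
    params: ModelParams,
    rng: np.random.Generator,
) -> Bout:
    """Sample one foraging bout from the current transition table.

    The bee starts at the nest and repeatedly samples its next flower from
    the current origin's row, with two masked outcomes resampled: the nest
    (a foraging bee heads home only once its crop is full) and the flower
    it has just departed (no immediate U-turns; returns to a recently
    emptied flower after at least one intervening visit are permitted and
    counted as revisits).  Masked resampling is equivalent to renormalising
    the row without the masked entries.  Once ``crop_capacity`` distinct
    flowers have been visited the crop is full and the bee flies straight
    back to the nest.  Landing on one member of a co-located pair collects
    both members' nectar (the pair shares one physical position and
    proxies a single double-reward flower).  If the transition cap is
    reached first the bout is flagged incomplete and closed via the nest.
    """
    params = params.resolve(array)
    d = array.distances
    crop = params.crop_capacity
    cap = params.max_transitions_per_bout
    # landing on one member of a co-located pair collects both flowers'
    # nectar at once: the pair shares a single physical position
    partner = {}
    for pair in array.colocated_pairs:
        a, b = sorted(pair)
        partner[a + 1] = b + 1
        partner[b + 1] = a + 1
    visits = [0]
    seen = set()
    length = 0.0
    revisits = 0
    here = 0
    prev = 0
    complete = False
    for _ in range(cap):
        nxt = -1
        for _attempt in range(1000):
            cand = table.sample_next(here, rng)
            if cand != 0 and cand != prev:
                nxt = cand
                break
        if nxt < 0:
            # every admissible successor is masked (degenerate geometry);
            # close the bout rather than spin forever
            break
        length += d[here, nxt]
        visits.append(nxt)
        prev, here = here, nxt
        if nxt in seen:
            revisits += 1
        else:
            seen.add(nxt)
            if nxt in partner:
                seen.add(partner[nxt])
            if len(seen) >= crop:
                complete = True
                break
    if here != 0:
        length += d[here, 0]
        visits.append(0)
    return Bout(
        visits=tuple(visits),
        length=length,
        distinct_flowers=len(seen),
        revisits=revisits,
        complete=complete,
    )


def qualifies_for_comparison(bout: Bout, params: ModelParams) -> bool:
    """A bout qualifies when it filled the crop.

    Only qualifying bouts enter the best-route comparison and can be
    reinforced; capped, incomplete bouts never do.
    """
    crop = params.crop_capacity
    return bout.complete and (crop is None or bout.distinct_flowers >= crop)


def reinforce(
    table: TransitionTable,
    bout: Bout,
    l_best: float,
    params: ModelParams,
) -> float:
    """Apply the route-comparison rule; returns the updated best length.

    If the qualifying bout's length is no longer than the best so far
    (ties reinforce), each *distinct* directed transition it traversed is
    multiplied by the enhancement factor once — regardless of traversal
    multiplicity — and the affected rows are renormalised in place.
    Otherwise the table is untouched.
    """
    if bout.length > l_best:
        return l_best
    transitions = {
        (bout.visits[k], bout.visits[k + 1]) for k in range(len(bout.visits) - 1)
    }
    table.multiply(transitions, params.enhancement_factor)
    return bout.length


@dataclass
class BeeRun:
    """A bee's full multi-bout history."""

    bouts: list[Bout]
    l_best_trace: list[float]
    best_route: tuple[int, ...] | None
    l_best: float
    first_optimal_bout: int | None
    stability_bout: int | None
    stability_bout_merged: int | None
    n_capped_bouts: int
    table: TransitionTable
    l_min: float | None = None

    @property
    def n_bouts(self) -> int:
        return len(self.bouts)

    def optimal_by(self, bout_index: int) -> bool:
        return self.first_optimal_bout is not None and self.first_optimal_bout <= bout_index

    def stable_by(self, bout_index: int, merge_reversals: bool = False) -> bool:
        s = self.stability_bout_merged if merge_reversals else self.stability_bout
        return s is not None and s <= bout_index


def _is_optimal_bout(bout: Bout, array: FlowerArray, crop: int, l_min: float) -> bool:
    # Optimal: the crop was filled with no revisit and the flower sequence
    # realises the shortest circuit length (reversals tie by symmetry).
    if not bout.complete or bout.revisits or 0 in bout.visits[1:-1]:
        return False
    seq = bout.flower_sequence
    if len(seq) != crop:
        return False
    return bout.length <= l_min * (1.0 + 1e-9)


def run_bee(
    array: FlowerArray,
    params: ModelParams,
    rng: np.random.Generator | None = None,
    l_min: float | None = None,
    compute_optimum: bool = True,
) -> BeeRun:
    """Simulate one bee for ``params.n_bouts`` consecutive bouts.

    Flowers replenish every bout; memory (the transition table) carries
    over with no overnight loss.  If ``l_min`` is not given and the array
    is small enough for exact computation, the shortest qualifying circuit
    (over the best crop-sized subset where the crop is limiting) is
    computed so that first-optimal and stability bouts can be recorded.
    Stability is the first of 3 consecutive identical optimal bouts.  A
    trapline has a habitual direction, so the primary index
    (``stability_bout``) does *not* merge a circuit with its reversal;
    ``stability_bout_merged`` treats a circuit and its reversal as the same
    route (both are equivalent for optimality, which is length-based).
    Direction takes far longer to lock in than the route itself, so the
    merged index is the relevant one at weak enhancement factors.
    """
    params = params.resolve(array)
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    if l_min is None and compute_optimum and array.n_flowers <= 12:
        if params.crop_capacity < array.n_flowers:
            l_min = _oracle.best_subset_circuit(array, params.crop_capacity).length
        else:
            l_min = _oracle.optimal_circuit(array).length

    table = init_transition_table(array, params)
    bouts: list[Bout] = []
    l_best_trace: list[float] = []
    l_best = np.inf
    best_route = None
    first_optimal = None
    stability = None
    stability_merged = None
    streak_seq, streak_len = None, 0
    mstreak_seq, mstreak_len = None, 0
    n_capped = 0

    for b in range(1, params.n_bouts + 1):
        bout = simulate_bout(table, array, params, rng)
        bouts.append(bout)
        if not bout.complete:
            n_capped += 1
        if qualifies_for_comparison(bout, params):
            new_best = reinforce(table, bout, l_best, params)
            if new_best < l_best or best_route is None:
                best_route = bout.flower_sequence
            l_best = new_best
        l_best_trace.append(l_best)

        if l_min is not None and _is_optimal_bout(bout, array, params.crop_capacity, l_min):
            if first_optimal is None:
                first_optimal = b
            seq = bout.flower_sequence
            if seq == streak_seq:
                streak_len += 1
            else:
                streak_seq, streak_len = seq, 1
            if streak_len >= 3 and stability is None:
                stability = b - 2
            mseq = min(seq, tuple(reversed(seq)))
            if mseq == mstreak_seq:
                mstreak_len += 1
            else:
                mstreak_seq, mstreak_len = mseq, 1
            if mstreak_len >= 3 and stability_merged is None:
                stability_merged = b - 2
        else:
            streak_seq, streak_len = None, 0
            mstreak_seq, mstreak_len = None, 0

    return BeeRun(
        bouts=bouts,
        l_best_trace=l_best_trace,
        best_route=best_route,
        l_best=float(l_best) if np.isfinite(l_best) else np.inf,
        first_optimal_bout=first_optimal,
        stability_bout=stability,
        stability_bout_merged=stability_merged,
        n_capped_bouts=n_capped,
        table=table,
        l_min=l_min,
    )


@dataclass
class CohortResult:
    """Independent seeded runs of many bees on one array, with summaries."""

    runs: list[BeeRun]
    array: FlowerArray
    params: ModelParams

    @property
    def n_bees(self) -> int:
        return len(self.runs)

    def fraction_optimal_by(self, bout: int) -> float:
        return float(np.mean([r.optimal_by(bout) for r in self.runs]))

    def fraction_stable_by(self, bout: int, merge_reversals: bool = False) -> float:
        return float(np.mean([r.stable_by(bout, merge_reversals) for r in self.runs]))

    def mean_best_ratio(self) -> float:
        """Cohort mean of L_best / L_min over bees with a finite best route."""
        ratios = [
            r.l_best / r.l_min
            for r in self.runs
            if r.l_min is not None and np.isfinite(r.l_best)
        ]
        if not ratios:
            raise ValueError("no bee completed a qualifying bout, or no exact optimum known")
        return float(np.mean(ratios))

    def summary(self):
        """Per-bout cohort fractions as a tidy DataFrame."""
        import pandas as pd

        n_bouts = self.params.resolve(self.array).n_bouts
        rows = []
        for b in range(1, n_bouts + 1):
            rows.append(
                {
                    "bout": b,
                    "fraction_optimal": self.fraction_optimal_by(b),
                    "fraction_stable": self.fraction_stable_by(b),
                    "mean_l_best": float(
                        np.mean(
                            [
                                r.l_best_trace[b - 1]
                                for r in self.runs
                                if np.isfinite(r.l_best_trace[b - 1])
                            ]
                        )
                    )
                    if any(np.isfinite(r.l_best_trace[b - 1]) for r in self.runs)
                    else np.nan,
                }
            )
        return pd.DataFrame(rows)


def run_cohort(
    array: FlowerArray,
    params: ModelParams,
    n_bees: int,
    l_min: float | None = None,
    compute_optimum: bool = True,
    seed_sequence: np.random.SeedSequence | None = None,
) -> CohortResult:
    """Run ``n_bees`` independent bees with per-bee streams spawned from the
    root seed (or an explicit :class:`numpy.random.SeedSequence`), so
    results are reproducible and order-independent."""
    if n_bees < 1:
        raise ValueError("n_bees must be >= 1")
    params = params.resolve(array)
    if l_min is None and compute_optimum and array.n_flowers <= 12:
        if params.crop_capacity < array.n_flowers:
            l_min = _oracle.best_subset_circuit(array, params.crop_capacity).length
        else:
            l_min = _oracle.optimal_circuit(array).length
    if seed_sequence is None:
        seed_sequence = np.random.SeedSequence(params.rng_seed)
    streams = seed_sequence.spawn(n_bees)
    runs = [
        run_bee(
            array, params, rng=np.random.default_rng(s), l_min=l_min,
            compute_optimum=compute_optimum,
        )
        for s in streams
    ]
    return CohortResult(runs=runs, array=array, params=params)
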