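"""Exact and heuristic baselines for route optimality.

Everything here answers one question: how short could a nest-to-nest
circuit over a set of flowers possibly be, and is a given route already
that short?  The exact solver is Held-Karp dynamic programming (feasible
to ~15 flowers); a brute-force permutation sweep cross-checks it on small
instances; the greedy nearest-neighbour tour provides the classical
reference ratio; and the all-pairs transposition test is the tractable
improvability statistic used where exact optimality is out of reach
(20 or more flowers).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np

from .arrays import FlowerArray

__all__ = [
    "OptimalRoute",
    "optimal_circuit",
    "brute_force_circuit",
    "best_subset_circuit",
    "nearest_neighbour_circuit",
    "pairwise_switch_improvable",
    "EXACT_LIMIT",
]

#: Largest subset size for which exact Held-Karp computation is attempted.
EXACT_LIMIT = 15


@dataclass(frozen=True)
class OptimalRoute:
    """A shortest nest-to-nest circuit over a flower subset.

    ``order`` lists flower indices; the nest is implicit at both ends.
    ``exact`` records whether the length is a proven optimum.  A circuit
    and its reversal have identical length; ``order`` is canonicalized to
    the lexicographically smaller of the two directions.
    """

    order: tuple[int, ...]
    length: float
    exact: bool = True

    def reversed(self) -> "OptimalRoute":
        return OptimalRoute(tuple(reversed(self.order)), self.length, self.exact)


def _canonical(order: tuple[int, ...]) -> tuple[int, ...]:
    rev = tuple(reversed(order))
    return min(order, rev)


def optimal_circuit(array: FlowerArray, subset=None) -> OptimalRoute:
    """Exact shortest nest -> subset permutation -> nest circuit (Held-Karp).

    ``subset`` is an iterable of flower indices (default: all flowers).
    Raises for subsets beyond :data:`EXACT_LIMIT` flowers: no silent
    heuristic fallback is provided, because every caller in this package
    that needs an approximate answer uses the improvability statistic
    instead.  Ties are broken deterministically (lexicographically smallest
    order among equals, reversal-merged).
    """
    subset = tuple(range(array.n_flowers)) if subset is None else tuple(subset)
    k = len(subset)
    if k < 1:
        raise ValueError("subset must contain at least one flower")
    if len(set(subset)) != k:
        raise ValueError("subset contains repeated flowers")
    if k > EXACT_LIMIT:
        raise ValueError(
            f"exact optimum limited to {EXACT_LIMIT} flowers (got {k}); "
            "use pairwise_switch_improvable for larger instances"
        )
    if k == 1:
        f = subset[0]
        return OptimalRoute((f,), 2.0 * array.nest_distance(f))

    # Held-Karp over the subset; node i in 0..k-1 maps to flower subset[i],
    # distance matrix rows/cols 1..k are flowers, 0 the nest.
    loc = np.concatenate([[0], np.asarray(subset, dtype=int) + 1])
    d = array.distances[np.ix_(loc, loc)]
    full = (1 << k) - 1
    INF = np.inf
    # dp[mask][j]: shortest path nest -> visits mask -> ends at flower j
    dp = np.full((1 << k, k), INF)
    parent = np.full((1 << k, k), -1, dtype=np.int32)
    for j in range(k):
        dp[1 << j, j] = d[0, j + 1]
    for mask in range(1, full + 1):
        row = dp[mask]
        for j in range(k):
            bit = 1 << j
            if not mask & bit or row[j] == INF:
                continue
            base = row[j]
            for m in range(k):
                if mask & (1 << m):
                    continue
                cand = base + d[j + 1, m + 1]
                nxt = mask | (1 << m)
                if cand < dp[nxt, m]:
                    dp[nxt, m] = cand
                    parent[nxt, m] = j
    closing = dp[full] + d[1:, 0]
    length = float(closing.min())
    last = int(closing.argmin())
    order = []
    mask = full
    while last >= 0:
        order.append(subset[last])
        prev = parent[mask, last]
        mask ^= 1 << last
        last = prev
    order = _canonical(tuple(reversed(order)))
    return OptimalRoute(order, length)


def brute_force_circuit(array: FlowerArray, subset=None) -> OptimalRoute:
    """Exhaustive permutation sweep; independent cross-check of Held-Karp.

    Tractable to ~9 flowers.  Permutations are scanned in lexicographic
    order with strict improvement, so the returned order is the
    lexicographically smallest optimum automatically.
    """
    subset = tuple(range(array.n_flowers)) if subset is None else tuple(subset)
    if len(subset) > 9:
        raise ValueError("brute force limited to 9 flowers")
    best, best_len = None, np.inf
    for perm in permutations(sorted(subset)):
        L = array.route_length(perm)
        if L < best_len:
            best, best_len = perm, L
    return OptimalRoute(_canonical(best), float(best_len))


def best_subset_circuit(array: FlowerArray, subset_size: int) -> OptimalRoute:
    """Shortest circuit over the best ``subset_size``-flower subset.

    Minimizes :func:`optimal_circuit` over all subsets of the given size —
    the target a crop-limited bee can aim for when it knows more flowers
    than it needs to fill its crop.
    """
    n = array.n_flowers
    if not 1 <= subset_size <= n:
        raise ValueError("subset_size must be between 1 and n_flowers")
    if n > 12:
        raise ValueError("subset enumeration limited to 12 flowers")
    best = None
    for subset in combinations(range(n), subset_size):
        route = optimal_circuit(array, subset)
        if best is None or route.length < best.length:
            best = route
    return best


def nearest_neighbour_circuit(array: FlowerArray) -> OptimalRoute:
    """Greedy tour: from the nest, always fly to the closest unvisited flower.

    Closes back at the nest after the last flower.  Ties break to the
    lowest flower index.  ``exact=False``: this is the heuristic baseline,
    not an optimum.
    """
    n = array.n_flowers
    d = array.distances
    unvisited = list(range(1, n + 1))
    here, order = 0, []
    while unvisited:
        nxt = min(unvisited, key=lambda j: (d[here, j], j))
        order.append(nxt - 1)
        unvisited.remove(nxt)
        here = nxt
    order = tuple(order)
    return OptimalRoute(order, array.route_length(order), exact=False)


def pairwise_switch_improvable(
    route, array: FlowerArray, allow_repeats: bool = False
):
    """Can the circuit be strictly shortened by transposing two visits?

    Tries all C(k, 2) transpositions of positions in the visit sequence
    (not only adjacent ones) and returns ``(improvable, best_switch)``
    where ``best_switch`` is ``(i, j, new_length)`` for the most improving
    transposition, or ``None``.  By default the route must visit each of
    its flowers exactly once; sequences with revisits are accepted with
    ``allow_repeats=True`` (positional transpositions remain well defined).

    An optimal circuit is never improvable; the converse fails — there are
    transposition-stable routes that are not optimal — which is why this is
    only an upper-bound test for optimality on large instances.
    """
    seq = np.asarray(route, dtype=int)
    k = len(seq)
    if k == 0:
        raise ValueError("empty route")
    if not allow_repeats and len(set(seq.tolist())) != k:
        raise ValueError("route revisits a flower; pass allow_repeats=True")
    loc = np.concatenate([[0], seq + 1, [0]])
    d = array.distances
    base = float(d[loc[:-1], loc[1:]].sum())
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    if not pairs:
        return False, None
    # evaluate all swapped circuits in one vectorized pass
    trials = np.tile(loc, (len(pairs), 1))
    idx = np.arange(len(pairs))
    ii = np.array([p[0] + 1 for p in pairs])
    jj = np.array([p[1] + 1 for p in pairs])
    tmp = trials[idx, ii].copy()
    trials[idx, ii] = trials[idx, jj]
    trials[idx, jj] = tmp
    lengths = d[trials[:, :-1], trials[:, 1:]].sum(axis=1)
    best_idx = int(lengths.argmin())
    best_len = float(lengths[best_idx])
    if best_len < base * (1.0 - 1e-12):
        i, j = pairs[best_idx]
        return True, (i, j, best_len)
    return False, None
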