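"""Route-sequence and transition-structure statistics.

Covers the three statistics used to confront the traplining model with
behavioural records: a similarity index between flower-visit sequences, a
standardized asymmetry index over directional transition counts, and
empirical rank p-values of an observation against a simulated null
distribution.  Also provides tidy per-cohort summaries (distinct routes,
revisits, visit-frequency histograms).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TransitionCounts",
    "NullDistribution",
    "similarity_index",
    "asymmetry_index",
    "transition_counts_from_sequences",
    "empirical_pvalue",
    "cohort_summaries",
]


# -- similarity index ---------------------------------------------------


def similarity_index(seq_a, seq_b) -> float:
    """Similarity between two flower-visit sequences, in [0, 1].

    Adopted convention (the historical index is cited in the literature
    without a printed formula): the number of ordered flower-to-flower
    transitions shared between the two sequences, counted with
    multiplicity, divided by the larger of the two sequences' transition
    counts.  This respects both visit order and sequence length, is
    symmetric, and meets the defining endpoints: 0 for sequences with no
    transition in common (e.g. 123 vs 456) and 1 only for identical
    sequences (e.g. 12345 vs 12345).  Single-visit sequences have no
    transitions; they score 1 if identical, else 0.
    """
    a, b = list(seq_a), list(seq_b)
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    ta = Counter(zip(a[:-1], a[1:]))
    tb = Counter(zip(b[:-1], b[1:]))
    denom = max(sum(ta.values()), sum(tb.values()))
    if denom == 0:
        return 1.0 if a == b else 0.0
    shared = sum((ta & tb).values())
    return shared / denom


# -- asymmetry index ----------------------------------------------------


@dataclass
class TransitionCounts:
    """Directional transition counts per unordered flower pair.

    ``counts[(i, j)]`` with ``i < j`` holds ``(n_ij, n_ji)``: the numbers
    of i->j and j->i moves accumulated over a stated window of bouts.
    """

    counts: dict = field(default_factory=dict)
    window: tuple[int, int] | None = None

    def add(self, i: int, j: int, n: int = 1) -> None:
        if i == j:
            raise ValueError("self-transitions carry no direction")
        a, b = (i, j) if i < j else (j, i)
        fwd, rev = self.counts.get((a, b), (0, 0))
        if i < j:
            fwd += n
        else:
            rev += n
        self.counts[(a, b)] = (fwd, rev)

    def relabelled(self, mapping) -> "TransitionCounts":
        out = TransitionCounts(window=self.window)
        for (i, j), (nij, nji) in self.counts.items():
            out.add(mapping[i], mapping[j], nij)
            out.add(mapping[j], mapping[i], nji)
        return out


def transition_counts_from_sequences(sequences, window=None) -> TransitionCounts:
    """Accumulate directional flower-to-flower transition counts over bouts."""
    tc = TransitionCounts(window=window)
    for seq in sequences:
        seq = list(seq)
        for i, j in zip(seq[:-1], seq[1:]):
            if i != j:
                tc.add(i, j)
    return tc


def pair_asymmetry_pvalue(n: int, total: int) -> float:
    """Two-tailed binomial probability of the observed directional split.

    Under a 1:1 expectation, ``P = min(1, 2 * Pr(X >= max(n, N - n)))``
    with ``X ~ Binomial(N, 1/2)``.  The simple doubled tail capped at 1 is
    used (no point-mass adjustment).  A perfectly balanced split gives
    ``P = 1``.
    """
    if not 0 <= n <= total:
        raise ValueError("need 0 <= n <= N")
    k = max(n, total - n)
    return float(min(1.0, 2.0 * stats.binom.sf(k - 1, total, 0.5)))


def asymmetry_index(counts: TransitionCounts, min_obs: int = 6):
    """Standardized asymmetry index over a set of flower pairs.

    For each unordered pair with ``N = n_ij + n_ji >= min_obs``
    observations, the two-tailed binomial probability ``P`` of the
    directional split is scored as ``-ln P``; the standardized index is
    the mean score over tested pairs (division by the number of pairs
    tested makes windows with different pair counts comparable).  Returns
    ``(index, n_pairs_tested)``; if no pair reaches ``min_obs`` the index
    is ``None`` — explicitly undefined, not zero.

    The per-pair ``-ln P`` score is an adopted convention (the historical
    definition survives only as an unrendered expression); it is invariant
    under flower relabelling and under flipping every pair's direction.
    """
    scores = []
    for (_, _), (nij, nji) in counts.counts.items():
        total = nij + nji
        if total < min_obs:
            continue
        scores.append(-np.log(pair_asymmetry_pvalue(nij, total)))
    if not scores:
        return None, 0
    return float(np.mean(scores)), len(scores)


# -- empirical p-values -------------------------------------------------


@dataclass
class NullDistribution:
    """Sorted metric values from repeated model runs (the null)."""

    name: str
    values: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        v = np.sort(np.asarray(self.values, dtype=float))
        if v.size == 0:
            raise ValueError("null distribution is empty")
        self.values = v

    @property
    def n_runs(self) -> int:
        return self.values.size


def empirical_pvalue(
    null: NullDistribution, observation: float, better_is_smaller: bool = True
) -> float:
    """Rank p-value of an observation against a simulated null.

    ``p`` is the fraction of null values at least as extreme (slower /
    worse) as the observation, with ties counted half (mid-p).  With
    ``better_is_smaller`` (e.g. bout counts, route lengths), an
    observation equal to the 70th-percentile-quickest point of the null
    yields p = 0.3; one quicker than every null value yields p = 1; one
    slower than all of them yields the smallest attainable value
    ``1 / (2 n_runs)`` rather than 0, since a rank statistic cannot
    certify impossibility.  The model is conventionally rejected below
    p = 0.05.
    """
    v = null.values
    n = v.size
    if better_is_smaller:
        worse = np.count_nonzero(v > observation)
    else:
        worse = np.count_nonzero(v < observation)
    ties = np.count_nonzero(v == observation)
    p = (worse + 0.5 * ties) / n
    return float(max(p, 0.5 / n))


# -- cohort summaries ---------------------------------------------------


def cohort_summaries(runs, window=None):
    """Tidy summaries of a list of bee runs.

    ``window`` is an inclusive 1-based bout range (default: all simulated
    bouts).  Returns a dict of DataFrames:

    ``per_bee``
        distinct-route count within the window (routes distinct as flower
        sequences), first-optimal and stability bouts, capped-bout count;
    ``per_bout``
        revisit counts and route lengths, one row per bee x bout;
    ``visit_frequency``
        per-flower visit-count histogram over the window: rows
        (flower, n_visits_in_a_bout, frequency);
    ``fractions``
        fraction of bees optimal / stable by each bout in the window.
    """
    if not runs:
        raise ValueError("no runs to summarise")
    n_bouts = runs[0].n_bouts
    lo, hi = window if window is not None else (1, n_bouts)
    if not (1 <= lo <= hi <= n_bouts):
        raise ValueError(f"window {window} outside simulated bouts 1..{n_bouts}")

    per_bee, per_bout, visit_rows = [], [], []
    hist = Counter()
    for bee, run in enumerate(runs):
        seqs = [b.flower_sequence for b in run.bouts[lo - 1 : hi]]
        per_bee.append(
            {
                "bee": bee,
                "distinct_routes": len(set(seqs)),
                "first_optimal_bout": run.first_optimal_bout,
                "stability_bout": run.stability_bout,
                "n_capped_bouts": run.n_capped_bouts,
                "l_best": run.l_best,
            }
        )
        for b_idx, bout in enumerate(run.bouts[lo - 1 : hi], start=lo):
            per_bout.append(
                {
                    "bee": bee,
                    "bout": b_idx,
                    "length": bout.length,
                    "revisits": bout.revisits,
                    "distinct_flowers": bout.distinct_flowers,
                    "complete": bout.complete,
                }
            )
            counts = Counter(bout.flower_sequence)
            n_flowers = len(run.table.probs) - 1
            for f in range(n_flowers):
                hist[(f, counts.get(f, 0))] += 1
    total_bouts = len(runs) * (hi - lo + 1)
    for (f, k), c in sorted(hist.items()):
        visit_rows.append(
            {"flower": f, "n_visits": k, "frequency": c / total_bouts}
        )
    fractions = pd.DataFrame(
        {
            "bout": np.arange(lo, hi + 1),
            "fraction_optimal": [
                float(np.mean([r.optimal_by(b) for r in runs])) for b in range(lo, hi + 1)
            ],
            "fraction_stable": [
                float(np.mean([r.stable_by(b) for r in runs])) for b in range(lo, hi + 1)
            ],
        }
    )
    return {
        "per_bee": pd.DataFrame(per_bee),
        "per_bout": pd.DataFrame(per_bout),
        "visit_frequency": pd.DataFrame(visit_rows),
        "fractions": fractions,
    }
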