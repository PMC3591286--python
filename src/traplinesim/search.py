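"""Loop-search model for locating a new or missing flower.

A searching bee flies out from the origin of its search along a straight
leg of uniform-random direction whose length is drawn from an exponential
distribution with mean ``lam``; it perceives the target flower if the leg
passes within a perception radius ``r`` of it, otherwise it retraces the
leg back to the origin and tries again.  The search is centred on the
origin because that is, initially, the most likely flower location.

The expected number of loops before success follows from extreme-value
reasoning: the search ends when the longest leg so far becomes comparable
with the flower distance ``R``, i.e. when ``n * Pr(l > R) ~ 1``.  For
exponential legs ``Pr(l > R) = exp(-R/lam)``, so ``n = exp(R/lam)`` and
the mean total path length (legs counted out and back) is

    <L> = 2 * n * lam = 2 * lam * exp(R / lam).

Minimising over ``lam``: ``d/dlam [lam * exp(R/lam)] =
exp(R/lam) * (1 - R/lam) = 0``, giving the optimum ``lam* = R`` with
``<L> = 2 e R`` — the mean outward leg should equal the expected flower
distance.  The closed form is an order-of-magnitude estimate, not an exact
expectation; simulations are compared with it under stated tolerances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SearchParams",
    "SearchPath",
    "simulate_search",
    "mean_search_length",
    "expected_loops",
    "optimal_loop_scale",
]


@dataclass(frozen=True)
class SearchParams:
    """Parameters of a loop search.

    lam
        Mean outward-leg length (metres); the scale of the exponential
        leg-length distribution.
    target_distance
        Distance ``R`` from the search origin to the flower (metres).
    perception_radius
        Direct-perception distance ``r`` (metres); must satisfy
        ``r < R`` or the search succeeds trivially from the origin.
    max_loops
        Cap on the number of loops; capped searches are flagged.
    """

    lam: float
    target_distance: float
    perception_radius: float = 0.0
    max_loops: int = 100_000
    rng_seed: int | None = None

    def __post_init__(self):
        if self.lam <= 0 or self.target_distance <= 0:
            raise ValueError("lam and target_distance must be positive")
        if self.perception_radius < 0:
            raise ValueError("perception radius must be non-negative")
        if self.max_loops < 1:
            raise ValueError("max_loops must be >= 1")


@dataclass(frozen=True)
class SearchPath:
    """One realised search: its loops, total length and outcome.

    ``loops`` holds ``(direction, leg_length)`` pairs; the final leg is
    truncated at first perception when the search succeeds.  Every leg is
    counted out and back (``total_length = 2 * sum of leg lengths``),
    matching the accounting of the closed-form mean.
    """

    loops: tuple[tuple[float, float], ...]
    total_length: float
    success: bool

    @property
    def n_loops(self) -> int:
        return len(self.loops)


def _interception_distance(direction: float, bearing: float, R: float, r: float):
    """Along-track distance at which a leg in ``direction`` first comes
    within ``r`` of a flower at polar position ``(R, bearing)``; None if the
    ray misses the perception disc."""
    if r >= R:
        return 0.0
    delta = direction - bearing
    cross = R * abs(np.sin(delta))
    along = R * np.cos(delta)
    if cross > r or along <= 0.0:
        return None
    return along - np.sqrt(r * r - cross * cross)


def simulate_search(
    params: SearchParams,
    flower_bearing: float = 0.0,
    rng: np.random.Generator | None = None,
    leg_sampler=None,
) -> SearchPath:
    """Simulate one loop search for a flower at ``(R, flower_bearing)``.

    Directions are i.i.d. uniform on the circle and leg lengths i.i.d.
    exponential with mean ``lam`` (pass ``leg_sampler(rng) -> length`` to
    swap in another leg-length family; the optimality of ``lam ~ R`` is
    not specific to exponential legs).  Perception is evaluated
    continuously along the outward leg (closest-approach test), not only
    at its endpoint; inbound retracing does not re-trigger perception,
    since the flower would already have been seen outbound along the same
    line.
    """
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    R, r, lam = params.target_distance, params.perception_radius, params.lam
    loops = []
    total = 0.0
    for _ in range(params.max_loops):
        direction = rng.uniform(0.0, 2.0 * np.pi)
        leg = rng.exponential(lam) if leg_sampler is None else leg_sampler(rng)
        hit = _interception_distance(direction, flower_bearing, R, r)
        if hit is not None and leg >= hit:
            loops.append((direction, hit))
            total += 2.0 * hit
            return SearchPath(tuple(loops), total, True)
        loops.append((direction, leg))
        total += 2.0 * leg
    return SearchPath(tuple(loops), total, False)


def expected_loops(lam: float, R: float) -> float:
    """Extreme-value estimate of the number of loops: ``n = exp(R / lam)``."""
    if lam <= 0 or R <= 0:
        raise ValueError("lam and R must be positive")
    return float(np.exp(R / lam))


def mean_search_length(lam: float, R: float) -> float:
    """Closed-form mean total search-path length ``2 lam exp(R / lam)``."""
    return 2.0 * lam * expected_loops(lam, R)


def optimal_loop_scale(R: float) -> float:
    """The mean leg length minimising the expected search cost: ``lam* = R``.

    Shorter loops almost always fall short of the flower and prolong the
    search; longer loops routinely overshoot where the flower is expected
    to be.  The balance point is legs as long, on average, as the expected
    flower distance.
    """
    if R <= 0:
        raise ValueError("R must be positive")
    return float(R)
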