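"""Flower-array geometries: the physical world a model bee forages in.

An array is a nest plus a set of flowers in continuous 2-D Cartesian
coordinates (metres).  All downstream machinery (transition priors, route
lengths, optimality oracles) works from the pairwise distance table held
here.  Generators cover the geometries used throughout the simulation
experiments: regular polygons, uniform-random square patches, clustered
patch grids, and hand-authored small-cage arrays in which proximity and
flight directionality are positively, negatively or independently linked.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "FlowerArray",
    "regular_polygon",
    "random_uniform",
    "patch_grid",
    "load_array",
    "save_array",
    "small_cage_array",
]

#: Relative tolerance for the triangle-inequality validation of distance tables.
_TRIANGLE_RTOL = 1e-9


@dataclass(frozen=True)
class FlowerArray:
    """Nest plus flowers with a validated pairwise distance table.

    Locations are indexed 0..n_flowers: index 0 is the nest, flower ``i``
    (0-based) is location ``i + 1``.  Distances are Euclidean, in metres.

    Parameters
    ----------
    nest : (2,) array-like
        Nest coordinates.
    flowers : (n, 2) array-like
        Flower coordinates, ordered; order defines flower indices.
    labels : sequence of str, optional
        Per-flower names; defaults to ``F1..Fn``.
    reward_unit : float
        Nectar units delivered by each flower per bout (default 1).
    colocated_pairs : frozenset of frozenset pairs of flower indices
        Flower pairs deliberately placed at identical coordinates (a proxy
        for a single double-reward flower).  Zero mutual distance is exempt
        from the positivity invariant; transitions within such a pair are
        forbidden downstream.
    high_reward : tuple of flower indices
        Flowers flagged as highly rewarding; the simulator may boost the
        initial nest-to-flower transition probability for these.
    patch_of : tuple of int, optional
        Patch membership per flower, for clustered (patch-grid) arrays.
    """

    nest: np.ndarray
    flowers: np.ndarray
    labels: tuple[str, ...] = ()
    reward_unit: float = 1.0
    colocated_pairs: frozenset = frozenset()
    high_reward: tuple[int, ...] = ()
    patch_of: tuple[int, ...] | None = None
    _distances: np.ndarray = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self):
        nest = np.asarray(self.nest, dtype=float).reshape(2)
        flowers = np.atleast_2d(np.asarray(self.flowers, dtype=float))
        if flowers.shape[0] < 1 or flowers.shape[1] != 2:
            raise ValueError("need at least 1 flower with 2-D coordinates")
        if not (np.isfinite(nest).all() and np.isfinite(flowers).all()):
            raise ValueError("coordinates must be finite")
        labels = tuple(self.labels) or tuple(f"F{i + 1}" for i in range(len(flowers)))
        if len(labels) != len(flowers):
            raise ValueError("labels must match the number of flowers")
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate flower labels")
        coloc = frozenset(frozenset(p) for p in self.colocated_pairs)
        object.__setattr__(self, "nest", nest)
        object.__setattr__(self, "flowers", flowers)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "colocated_pairs", coloc)
        object.__setattr__(self, "high_reward", tuple(self.high_reward))
        if self.patch_of is not None:
            object.__setattr__(self, "patch_of", tuple(self.patch_of))

        pts = self.points
        dist = cdist(pts, pts)
        n_loc = len(pts)
        for a in range(n_loc):
            for b in range(a + 1, n_loc):
                if dist[a, b] <= 0.0:
                    pair = frozenset((a - 1, b - 1))
                    if a >= 1 and b >= 1 and pair in coloc:
                        continue
                    raise ValueError(
                        f"locations {a} and {b} are coincident; only flagged "
                        "co-located flower pairs may share coordinates"
                    )
        # Euclidean tables satisfy these by construction; the checks guard
        # against future non-Euclidean extensions and NaN poisoning.
        if not np.allclose(dist, dist.T) or np.any(np.diag(dist) != 0.0):
            raise ValueError("distance table must be symmetric with zero diagonal")
        if n_loc <= 50:
            slack = dist[:, :, None] + dist[None, :, :] - dist[:, None, :]
            if slack.min() < -_TRIANGLE_RTOL * dist.max():
                raise ValueError("distance table violates the triangle inequality")
        object.__setattr__(self, "_distances", dist)

    # -- basic geometry -------------------------------------------------

    @property
    def n_flowers(self) -> int:
        return len(self.flowers)

    @property
    def points(self) -> np.ndarray:
        """All location coordinates, nest first: shape (n_flowers + 1, 2)."""
        return np.vstack([self.nest[None, :], self.flowers])

    @property
    def distances(self) -> np.ndarray:
        """Pairwise distance table over locations (nest = row/column 0)."""
        return self._distances

    def flower_distance(self, i: int, j: int) -> float:
        """Distance between flowers ``i`` and ``j`` (flower indices)."""
        return float(self._distances[i + 1, j + 1])

    def nest_distance(self, i: int) -> float:
        return float(self._distances[0, i + 1])

    def route_length(self, flower_sequence) -> float:
        """Length of the nest-to-nest circuit visiting ``flower_sequence``.

        The sequence uses flower indices; the nest is prepended and appended.
        """
        seq = np.asarray(flower_sequence, dtype=int) + 1
        loc = np.concatenate([[0], seq, [0]])
        return float(self._distances[loc[:-1], loc[1:]].sum())

    def scaled(self, c: float) -> "FlowerArray":
        """Return a copy with all coordinates multiplied by ``c`` > 0."""
        if c <= 0:
            raise ValueError("scale factor must be positive")
        return FlowerArray(
            nest=self.nest * c,
            flowers=self.flowers * c,
            labels=self.labels,
            reward_unit=self.reward_unit,
            colocated_pairs=self.colocated_pairs,
            high_reward=self.high_reward,
            patch_of=self.patch_of,
        )


# -- generators ---------------------------------------------------------


def regular_polygon(
    n_vertices: int,
    side_length: float,
    nest_at="centroid",
) -> FlowerArray:
    """Flowers on the vertices of a regular polygon.

    ``nest_at`` is ``"centroid"`` or an explicit ``(x, y)`` point.  The
    circumradius follows from the side length as ``s / (2 sin(pi/n))``; a
    pentagon with 5 m sides therefore has circumradius ~4.2533 m.  A nest
    coincident with a flower is rejected: offset it instead.
    """
    if n_vertices < 3:
        raise ValueError("a polygon needs at least 3 vertices")
    if side_length <= 0:
        raise ValueError("side length must be positive")
    radius = side_length / (2.0 * np.sin(np.pi / n_vertices))
    angles = 2.0 * np.pi * np.arange(n_vertices) / n_vertices
    flowers = radius * np.column_stack([np.cos(angles), np.sin(angles)])
    if isinstance(nest_at, str):
        if nest_at == "centroid":
            nest = np.zeros(2)
        elif nest_at == "vertex":
            # Degenerate on purpose: triggers the coincident-location error so
            # callers learn to supply an offset point instead.
            nest = flowers[0].copy()
        else:
            raise ValueError(f"unknown nest placement {nest_at!r}")
    else:
        nest = np.asarray(nest_at, dtype=float)
    return FlowerArray(nest=nest, flowers=flowers)


def random_uniform(
    n_flowers: int,
    patch_side: float,
    nest_at=(0.0, 0.0),
    rng_seed: int | None = None,
    min_separation: float | None = None,
) -> FlowerArray:
    """Flowers i.i.d. uniform on a square patch ``[0, patch_side]^2``.

    Degenerate draws in which any two locations (nest included) fall closer
    than ``min_separation`` (default ``patch_side / 1000``) are resampled
    wholesale, so the output never contains quasi-coincident flowers that
    would blow up the inverse-square transition prior.
    """
    if n_flowers < 1:
        raise ValueError("need at least 1 flower")
    if patch_side <= 0:
        raise ValueError("patch side must be positive")
    if min_separation is None:
        min_separation = patch_side / 1000.0
    rng = np.random.default_rng(rng_seed)
    nest = np.asarray(nest_at, dtype=float)
    while True:
        flowers = rng.uniform(0.0, patch_side, size=(n_flowers, 2))
        pts = np.vstack([nest[None, :], flowers])
        d = cdist(pts, pts)
        np.fill_diagonal(d, np.inf)
        if d.min() >= min_separation:
            return FlowerArray(nest=nest, flowers=flowers)


def patch_grid(
    patch_positions,
    flowers_per_patch: int,
    patch_radius: float,
    nest_at=(0.5, 0.5),
    rng_seed: int | None = None,
) -> FlowerArray:
    """Flowers clustered in discs around patch centres.

    Patches must not overlap: every pair of centres must be separated by
    more than ``2 * patch_radius``.  Patch membership is recorded per
    flower in ``patch_of``.
    """
    centres = np.atleast_2d(np.asarray(patch_positions, dtype=float))
    n_patches = len(centres)
    if flowers_per_patch < 1 or patch_radius <= 0:
        raise ValueError("need flowers_per_patch >= 1 and patch_radius > 0")
    if n_patches >= 2:
        d = cdist(centres, centres)
        np.fill_diagonal(d, np.inf)
        if d.min() <= 2.0 * patch_radius:
            raise ValueError("patches overlap: centre separation must exceed 2*radius")
    rng = np.random.default_rng(rng_seed)
    flowers, membership = [], []
    for p, centre in enumerate(centres):
        # uniform in the disc via rejection from the bounding square
        placed = 0
        while placed < flowers_per_patch:
            xy = rng.uniform(-patch_radius, patch_radius, size=2)
            if np.hypot(*xy) <= patch_radius:
                flowers.append(centre + xy)
                membership.append(p)
                placed += 1
    return FlowerArray(
        nest=np.asarray(nest_at, dtype=float),
        flowers=np.asarray(flowers),
        patch_of=tuple(membership),
    )


# -- persistence --------------------------------------------------------

NEST_LABEL = "NEST"


def save_array(array: FlowerArray, path) -> None:
    """Write an array to CSV (``label,x,y``; nest row labelled NEST) or JSON.

    The format is chosen from the file suffix.  Floats are written with
    ``repr`` precision so a save/load round trip is bit-exact.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "nest": [float(v) for v in array.nest],
            "labels": list(array.labels),
            "flowers": [[float(x), float(y)] for x, y in array.flowers],
            "reward_unit": array.reward_unit,
            "colocated_pairs": [sorted(p) for p in array.colocated_pairs],
            "high_reward": list(array.high_reward),
            "patch_of": list(array.patch_of) if array.patch_of is not None else None,
        }
        path.write_text(json.dumps(payload, indent=1))
        return
    rows = ["label,x,y", f"{NEST_LABEL},{float(array.nest[0])!r},{float(array.nest[1])!r}"]
    for lab, (x, y) in zip(array.labels, array.flowers):
        rows.append(f"{lab},{float(x)!r},{float(y)!r}")
    path.write_text("\n".join(rows) + "\n")


def load_array(path) -> FlowerArray:
    """Read a flower array saved by :func:`save_array` (CSV or JSON).

    CSV carries coordinates only; exact duplicate coordinates are auto-
    flagged as co-located pairs so reward-proxy arrays survive the round
    trip.  JSON carries all metadata explicitly.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        return FlowerArray(
            nest=np.asarray(payload["nest"], dtype=float),
            flowers=np.asarray(payload["flowers"], dtype=float),
            labels=tuple(payload.get("labels") or ()),
            reward_unit=payload.get("reward_unit", 1.0),
            colocated_pairs=frozenset(
                frozenset(p) for p in payload.get("colocated_pairs", [])
            ),
            high_reward=tuple(payload.get("high_reward", ())),
            patch_of=tuple(payload["patch_of"]) if payload.get("patch_of") else None,
        )
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"label", "x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"array CSV is missing columns: {sorted(missing)}")
    if not np.issubdtype(df["x"].dtype, np.number) or not np.issubdtype(
        df["y"].dtype, np.number
    ):
        raise ValueError("array CSV has non-numeric coordinates")
    is_nest = df["label"] == NEST_LABEL
    if is_nest.sum() != 1:
        raise ValueError(f"array CSV must contain exactly one {NEST_LABEL!r} row")
    nest = df.loc[is_nest, ["x", "y"]].to_numpy(dtype=float)[0]
    fl = df.loc[~is_nest]
    flowers = fl[["x", "y"]].to_numpy(dtype=float)
    coloc = set()
    for a in range(len(flowers)):
        for b in range(a + 1, len(flowers)):
            if np.array_equal(flowers[a], flowers[b]):
                coloc.add(frozenset((a, b)))
    return FlowerArray(
        nest=nest,
        flowers=flowers,
        labels=tuple(fl["label"].astype(str)),
        colocated_pairs=frozenset(coloc),
    )


# -- hand-authored small-cage arrays ------------------------------------

_CAGE_KINDS = ("positive", "independent", "negative")


def small_cage_array(kind: str) -> FlowerArray:
    """One of three hand-authored 10-flower flight-cage geometries.

    These are synthetic approximations of the classic small-cage designs in
    which flower proximity and flight directionality are linked:

    ``positive``
        flowers along an open arc with the nest closing the loop, so the
        nearest neighbour lies straight ahead and short transitions chain
        into the optimal circuit;
    ``independent``
        flowers on the outline of a triangle: still a loop, but corners and
        near-equal chords decouple proximity from the direction that
        continues a good route;
    ``negative``
        a two-row ladder with tight cross-row rungs, so the shortest
        transitions (the rungs) cut across the optimal perimeter circuit
        and chaining them produces long zigzag routes.

    The exact published coordinates are not available; these fixtures
    reproduce the qualitative geometric character only and are used for
    ordering comparisons, never for quantitative claims.
    """
    if kind not in _CAGE_KINDS:
        raise ValueError(f"kind must be one of {_CAGE_KINDS}")
    ref = resources.files("traplinesim.data").joinpath(f"synthetic_array_{kind}.csv")
    with resources.as_file(ref) as p:
        return load_array(p)
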