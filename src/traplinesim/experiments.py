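"""Config-driven simulation experiments.

Named, seeded recipes covering the package's standard computational
experiments: approximation quality on random travelling-salesman-style
arrays, the transposition-improvability statistic at 20 flowers,
crop-limited subset selection, reward prioritization with a co-located
flower pair, enhancement-factor sweeps, the three small-cage array types,
and patchily distributed resources.  Full-scale cohorts default to 100
random arrangements x 100 bees; a scale factor shrinks both for quick
runs while keeping the recipe itself fixed.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .arrays import FlowerArray, patch_grid, random_uniform, regular_polygon, small_cage_array
from .heuristic import ModelParams, run_cohort
from .oracle import best_subset_circuit, brute_force_circuit, optimal_circuit, pairwise_switch_improvable

__all__ = [
    "ExperimentSpec",
    "shipped_specs",
    "run_experiment",
    "make_array",
    "tsp_ratio_experiment",
    "switch_improvability_experiment",
    "crop_subset_experiment",
    "stability_experiment",
    "reward_priority_experiment",
    "patch_order_experiment",
]


# -- array construction from a serializable description ------------------


def make_array(desc: dict, seed=None) -> FlowerArray:
    """Build a :class:`FlowerArray` from a serializable description.

    ``desc["generator"]`` selects the builder; remaining keys are its
    parameters.  Stochastic builders take their seed from ``seed``.
    """
    desc = dict(desc)
    gen = desc.pop("generator")
    if gen == "random_uniform":
        return random_uniform(rng_seed=seed, **desc)
    if gen == "regular_polygon":
        return regular_polygon(**desc)
    if gen == "patch_grid":
        return patch_grid(rng_seed=seed, **desc)
    if gen == "small_cage":
        return small_cage_array(desc["kind"])
    if gen == "colocated_pair":
        return colocated_pair_array(rng_seed=seed, **desc)
    raise ValueError(f"unknown array generator {gen!r}")


def colocated_pair_array(
    n_flowers: int = 8,
    patch_side: float = 25.0,
    nest_at=(0.0, 0.0),
    rng_seed=None,
) -> FlowerArray:
    """Random uniform array whose last two flowers are co-located.

    The co-located pair sits at a single uniform-random position and
    proxies one highly rewarding (double-reward) flower; both members are
    flagged high-reward so the nest->flower prior boost applies to them.
    """
    base = random_uniform(n_flowers - 1, patch_side, nest_at=nest_at, rng_seed=rng_seed)
    flowers = np.vstack([base.flowers, base.flowers[-1]])
    pair = (n_flowers - 2, n_flowers - 1)
    return FlowerArray(
        nest=base.nest,
        flowers=flowers,
        colocated_pairs=frozenset([frozenset(pair)]),
        high_reward=pair,
    )


# -- spec ----------------------------------------------------------------


@dataclass(frozen=True)
class ExperimentSpec:
    """A named, fully serializable experiment recipe.

    ``sweep`` maps parameter names (model parameter names, or the special
    key ``n_flowers`` of the array description) to lists of values; the
    experiment runs the full cross product.  ``analysis`` selects what is
    measured per cohort.  Cohort sizes are full-scale defaults; callers
    shrink them with a scale factor at run time, never by editing the spec.
    """

    name: str
    array: dict
    model: dict
    analysis: str
    n_arrangements: int = 100
    n_bees: int = 100
    sweep: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentSpec":
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "ExperimentSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def scaled_sizes(self, scale: float) -> tuple[int, int]:
        if not 0 < scale <= 1:
            raise ValueError("scale must be in (0, 1]")
        return (
            max(1, round(self.n_arrangements * scale)),
            max(1, round(self.n_bees * scale)),
        )


def shipped_specs() -> dict[str, ExperimentSpec]:
    """The stable, documented set of named experiment recipes."""
    specs = [
        ExperimentSpec(
            name="factor_sweep",
            array={"generator": "regular_polygon", "n_vertices": 5, "side_length": 5.0,
                   "nest_at": "centroid"},
            model={"n_bouts": 65},
            analysis="stability",
            n_arrangements=1,
            sweep={"enhancement_factor": [1.01, 1.1, 1.5, 2.0, 4.0]},
        ),
        ExperimentSpec(
            name="array_types",
            array={"generator": "small_cage", "kind": "positive"},
            model={"n_bouts": 65},
            analysis="stability",
            n_arrangements=1,
            sweep={"kind": ["positive", "independent", "negative"],
                   "enhancement_factor": [1.1, 1.5]},
        ),
        ExperimentSpec(
            name="random_tsp",
            array={"generator": "random_uniform", "n_flowers": 10, "patch_side": 25.0},
            model={"enhancement_factor": 2.0, "n_bouts": 65},
            analysis="tsp_ratio",
            sweep={"n_flowers": [4, 5, 6, 7, 8, 9, 10]},
        ),
        ExperimentSpec(
            name="switch20",
            array={"generator": "random_uniform", "n_flowers": 20, "patch_side": 25.0},
            model={"enhancement_factor": 2.0, "n_bouts": 65},
            analysis="switch_improvability",
            sweep={"n_bouts": [65, 130]},
        ),
        ExperimentSpec(
            name="patches",
            array={"generator": "patch_grid",
                   "patch_positions": [[0.0, 0.0], [25.0, 0.0], [25.0, 25.0], [0.0, 25.0]],
                   "flowers_per_patch": 3, "patch_radius": 0.5,
                   "nest_at": [12.5, 12.5]},
            model={"enhancement_factor": 2.0, "n_bouts": 65},
            analysis="patch_order",
            n_arrangements=20,
        ),
        ExperimentSpec(
            name="crop_subset",
            array={"generator": "random_uniform", "n_flowers": 8, "patch_side": 25.0},
            model={"enhancement_factor": 2.0, "n_bouts": 65, "crop_capacity": 4},
            analysis="crop_subset",
            sweep={"crop_capacity": [2, 3, 4, 5, 6, 7]},
        ),
        ExperimentSpec(
            name="reward_priority",
            array={"generator": "colocated_pair", "n_flowers": 8, "patch_side": 25.0},
            model={"enhancement_factor": 2.0, "n_bouts": 65, "crop_capacity": 4,
                   "reward_priority_boost": 4.0},
            analysis="reward_priority",
            sweep={"crop_capacity": [2, 3, 4, 5, 6]},
        ),
    ]
    return {s.name: s for s in specs}


# -- core cohort analyses ------------------------------------------------


def _arrangement_streams(seed, n_arrangements):
    root = np.random.SeedSequence(seed)
    for child in root.spawn(n_arrangements):
        arr_ss, bee_ss = child.spawn(2)
        yield arr_ss, bee_ss


def tsp_ratio_experiment(
    n_flowers: int,
    n_arrangements: int,
    n_bees: int,
    params: ModelParams,
    patch_side: float = 25.0,
    seed=None,
) -> dict:
    """Mean best-route length over exact optimum across a cohort.

    For each random arrangement the exact shortest circuit is computed;
    each bee contributes its best-found complete route length divided by
    that optimum.  Also reports the fraction of bees that found an optimal
    route and the fraction within 10% of it.
    """
    ratios, optimal, near = [], [], []
    for arr_ss, bee_ss in _arrangement_streams(seed, n_arrangements):
        array = random_uniform(n_flowers, patch_side, rng_seed=arr_ss)
        l_min = optimal_circuit(array).length
        cohort = run_cohort(array, params, n_bees, l_min=l_min, seed_sequence=bee_ss)
        for run in cohort.runs:
            if not math.isfinite(run.l_best):
                continue
            ratio = run.l_best / l_min
            ratios.append(ratio)
            optimal.append(ratio <= 1.0 + 1e-9)
            near.append(ratio <= 1.10)
    return {
        "mean_ratio": float(np.mean(ratios)),
        "fraction_optimal": float(np.mean(optimal)),
        "fraction_within_10pct": float(np.mean(near)),
        "n_bees_counted": len(ratios),
    }


def switch_improvability_experiment(
    n_flowers: int,
    n_arrangements: int,
    n_bees: int,
    params: ModelParams,
    patch_side: float = 25.0,
    seed=None,
) -> dict:
    """Percentage of best-found routes improvable by one transposition.

    Used where exact optimality is computationally out of reach (20 or
    more flowers): each bee's shortest found route is tested against all
    C(k, 2) transpositions of its visit sequence.
    """
    improvable, counted = 0, 0
    for arr_ss, bee_ss in _arrangement_streams(seed, n_arrangements):
        array = random_uniform(n_flowers, patch_side, rng_seed=arr_ss)
        cohort = run_cohort(array, params, n_bees, compute_optimum=False, seed_sequence=bee_ss)
        for run in cohort.runs:
            if run.best_route is None:
                continue
            counted += 1
            flag, _ = pairwise_switch_improvable(run.best_route, array, allow_repeats=True)
            improvable += flag
    return {
        "percent_improvable": 100.0 * improvable / counted,
        "n_bees_counted": counted,
    }


def crop_subset_experiment(
    n_flowers: int,
    crop_capacity: int,
    n_arrangements: int,
    n_bees: int,
    params: ModelParams,
    patch_side: float = 25.0,
    seed=None,
) -> dict:
    """Fraction of bees that find the best crop-sized subset circuit.

    A bee succeeds if any bout realises the minimum-length nest-to-nest
    circuit over *all* subsets of ``crop_capacity`` flowers (exhaustive
    subset enumeration + exact circuits).
    """
    params = ModelParams(**{**_params_dict(params), "crop_capacity": crop_capacity})
    found = []
    for arr_ss, bee_ss in _arrangement_streams(seed, n_arrangements):
        array = random_uniform(n_flowers, patch_side, rng_seed=arr_ss)
        l_min = best_subset_circuit(array, crop_capacity).length
        cohort = run_cohort(array, params, n_bees, l_min=l_min, seed_sequence=bee_ss)
        for run in cohort.runs:
            found.append(run.first_optimal_bout is not None)
    return {
        "fraction_optimal": float(np.mean(found)),
        "n_bees_counted": len(found),
    }


def stability_experiment(
    array: FlowerArray,
    params: ModelParams,
    n_bees: int,
    seed=None,
) -> dict:
    """Fractions of bees with optimal / stable routes on one fixed array.

    Stability is reported both with the habitual-direction requirement
    (``fraction_stable``) and with a circuit and its reversal counted as
    the same trapline (``fraction_stable_merged``); route identity locks
    in long before direction does at weak enhancement factors.
    """
    ss = np.random.SeedSequence(seed)
    cohort = run_cohort(array, params, n_bees, seed_sequence=ss)
    n_bouts = params.resolve(array).n_bouts
    return {
        "fraction_optimal": cohort.fraction_optimal_by(n_bouts),
        "fraction_stable": cohort.fraction_stable_by(n_bouts),
        "fraction_stable_merged": cohort.fraction_stable_by(n_bouts, merge_reversals=True),
        "n_bees_counted": n_bees,
    }


def reward_priority_experiment(
    crop_capacity: int,
    n_arrangements: int,
    n_bees: int,
    params: ModelParams,
    n_flowers: int = 8,
    patch_side: float = 25.0,
    seed=None,
) -> dict:
    """Visit frequency of the high-reward (co-located pair) flower.

    Reports the mean, over bees and late bouts (second half), of the share
    of flower visits that land on the co-located pair — the prioritization
    signal.  As the crop demands more flowers the share of attention the
    most rewarding site can command shrinks toward its fair share.
    """
    params = ModelParams(**{**_params_dict(params), "crop_capacity": crop_capacity})
    freqs = []
    for arr_ss, bee_ss in _arrangement_streams(seed, n_arrangements):
        array = colocated_pair_array(n_flowers, patch_side, rng_seed=arr_ss)
        pair = set(array.high_reward)
        cohort = run_cohort(array, params, n_bees, compute_optimum=False, seed_sequence=bee_ss)
        n_bouts = params.resolve(array).n_bouts
        half = n_bouts // 2
        for run in cohort.runs:
            late = run.bouts[half:]
            visits = [f for b in late for f in b.flower_sequence]
            if not visits:
                continue
            freqs.append(sum(f in pair for f in visits) / len(visits))
    return {"mean_high_reward_visit_frequency": float(np.mean(freqs)),
            "n_bees_counted": len(freqs)}


def patch_order_experiment(
    n_arrangements: int,
    n_bees: int,
    params: ModelParams,
    patch_positions=((0.0, 0.0), (25.0, 0.0), (25.0, 25.0), (0.0, 25.0)),
    flowers_per_patch: int = 3,
    patch_radius: float = 0.5,
    nest_at=(12.5, 12.5),
    seed=None,
) -> dict:
    """Optimal ordering between patches versus within patches.

    A bout is *inter-patch optimal* when, collapsing consecutive visits to
    the same patch, each patch is visited exactly once in a shortest
    cyclic order of the patch centres (clockwise or anticlockwise).  It is
    *intra-patch optimal* when additionally every patch is covered in a
    single consecutive block whose internal order is a shortest open path
    within the patch.  Travel between patches dominates the route length,
    so optimal inter-patch order is expected to be much more frequent.
    """
    centres = np.asarray(patch_positions, dtype=float)
    inter, intra, total = 0, 0, 0
    for arr_ss, bee_ss in _arrangement_streams(seed, n_arrangements):
        array = patch_grid(centres, flowers_per_patch, patch_radius,
                           nest_at=nest_at, rng_seed=arr_ss)
        centre_array = FlowerArray(nest=np.asarray(nest_at, float), flowers=centres)
        best_patch_order = brute_force_circuit(centre_array).order
        patch_of = np.asarray(array.patch_of)
        cohort = run_cohort(array, params, n_bees, compute_optimum=False, seed_sequence=bee_ss)
        for run in cohort.runs:
            for bout in run.bouts:
                if not bout.complete:
                    continue
                total += 1
                seq = bout.flower_sequence
                pseq = [patch_of[f] for f in seq]
                collapsed = [p for p, _ in itertools.groupby(pseq)]
                ok_inter = (
                    len(collapsed) == len(centres)
                    and len(set(collapsed)) == len(centres)
                    and _same_cycle(tuple(collapsed), best_patch_order)
                )
                inter += ok_inter
                if ok_inter and not bout.revisits:
                    intra += all(
                        _block_is_shortest_path(seq, pseq, p, array)
                        for p in range(len(centres))
                    )
    return {
        "fraction_inter_patch_optimal": inter / total,
        "fraction_intra_patch_optimal": intra / total,
        "n_bouts_counted": total,
    }


def _same_cycle(a: tuple, b: tuple) -> bool:
    """Cyclic equality of two permutations, reversal-merged."""
    if len(a) != len(b):
        return False
    doubled = b + b
    rev = tuple(reversed(b)) + tuple(reversed(b))
    return any(doubled[i : i + len(a)] == a for i in range(len(b))) or any(
        rev[i : i + len(a)] == a for i in range(len(b))
    )


def _block_is_shortest_path(seq, pseq, patch, array) -> bool:
    idx = [k for k, p in enumerate(pseq) if p == patch]
    if idx[-1] - idx[0] != len(idx) - 1:
        return False  # patch not covered in one consecutive block
    block = [seq[k] for k in idx]
    d = array.distances
    loc = np.asarray(block, dtype=int) + 1
    length = float(d[loc[:-1], loc[1:]].sum())
    best = min(
        sum(d[perm[k] + 1, perm[k + 1] + 1] for k in range(len(perm) - 1))
        for perm in itertools.permutations(block)
    )
    return length <= best + 1e-12


def _params_dict(params: ModelParams) -> dict:
    return {
        "enhancement_factor": params.enhancement_factor,
        "n_bouts": params.n_bouts,
        "distance_exponent": params.distance_exponent,
        "crop_capacity": params.crop_capacity,
        "reward_priority_boost": params.reward_priority_boost,
        "max_transitions_per_bout": params.max_transitions_per_bout,
        "rng_seed": params.rng_seed,
    }


# -- generic runner ------------------------------------------------------


def _sweep_points(spec: ExperimentSpec):
    if not spec.sweep:
        yield {}
        return
    keys = sorted(spec.sweep)
    for combo in itertools.product(*(spec.sweep[k] for k in keys)):
        yield dict(zip(keys, combo))


def run_experiment(
    spec: ExperimentSpec,
    out_dir,
    seed: int = 0,
    scale: float = 1.0,
) -> pd.DataFrame:
    """Execute a recipe and write its results bundle.

    Runs every sweep point at ``scale`` times the full cohort sizes,
    writes one tidy CSV of results plus a manifest recording the spec,
    seed, scale and package version, and returns the results frame.
    Completed sweep points are checkpointed (``state.json``) so an
    interrupted run resumes without recomputing them.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n_arr, n_bees = spec.scaled_sizes(scale)
    state_path = out / "state.json"
    done: dict = {}
    if state_path.exists():
        done = json.loads(state_path.read_text())
        if done.get("_manifest", {}).get("seed") != seed or done.get("_manifest", {}).get(
            "scale"
        ) != scale:
            done = {}

    rows = []
    for k, point in enumerate(_sweep_points(spec)):
        key = json.dumps(point, sort_keys=True)
        if key in done:
            rows.append(done[key])
            continue
        result = _run_point(spec, point, n_arr, n_bees, seed=seed + k)
        row = {**point, **result}
        rows.append(row)
        done[key] = row
        done["_manifest"] = {"seed": seed, "scale": scale}
        state_path.write_text(json.dumps(done, indent=1))

    df = pd.DataFrame(rows)
    df.to_csv(out / "results.csv", index=False)
    manifest = {
        "spec": spec.to_dict(),
        "seed": seed,
        "scale": scale,
        "n_arrangements": n_arr,
        "n_bees": n_bees,
        "version": __version__,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return df


def _run_point(spec, point, n_arr, n_bees, seed):
    array_desc = dict(spec.array)
    model_kwargs = dict(spec.model)
    for k, v in point.items():
        if k in ("n_flowers", "kind"):
            array_desc[k] = v
        else:
            model_kwargs[k] = v
    params = ModelParams(**model_kwargs)

    if spec.analysis == "tsp_ratio":
        return tsp_ratio_experiment(
            array_desc["n_flowers"], n_arr, n_bees, params,
            patch_side=array_desc.get("patch_side", 25.0), seed=seed,
        )
    if spec.analysis == "switch_improvability":
        return switch_improvability_experiment(
            array_desc["n_flowers"], n_arr, n_bees, params,
            patch_side=array_desc.get("patch_side", 25.0), seed=seed,
        )
    if spec.analysis == "crop_subset":
        return crop_subset_experiment(
            array_desc["n_flowers"], params.crop_capacity, n_arr, n_bees, params,
            patch_side=array_desc.get("patch_side", 25.0), seed=seed,
        )
    if spec.analysis == "stability":
        array = make_array(array_desc, seed=seed)
        return stability_experiment(array, params, n_bees, seed=seed)
    if spec.analysis == "reward_priority":
        return reward_priority_experiment(
            params.crop_capacity, n_arr, n_bees, params,
            n_flowers=array_desc.get("n_flowers", 8),
            patch_side=array_desc.get("patch_side", 25.0), seed=seed,
        )
    if spec.analysis == "patch_order":
        return patch_order_experiment(
            n_arr, n_bees, params,
            patch_positions=array_desc["patch_positions"],
            flowers_per_patch=array_desc["flowers_per_patch"],
            patch_radius=array_desc["patch_radius"],
            nest_at=array_desc.get("nest_at", (12.5, 12.5)),
            seed=seed,
        )
    raise ValueError(f"unknown analysis {spec.analysis!r}")
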