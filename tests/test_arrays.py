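"""Geometry generators, persistence and invariants of flower arrays."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from traplinesim import (
    FlowerArray,
    load_array,
    patch_grid,
    random_uniform,
    regular_polygon,
    save_array,
    small_cage_array,
)


class TestRegularPolygon:
    def test_pentagon_side_lengths_and_circumradius(self):
        arr = regular_polygon(5, 5.0, nest_at="centroid")
        # closed-form circumradius s / (2 sin(pi/5))
        expected_r = 5.0 / (2.0 * np.sin(np.pi / 5))
        assert expected_r == pytest.approx(4.253254, abs=1e-6)
        radii = np.linalg.norm(arr.flowers, axis=1)
        assert radii == pytest.approx(expected_r)
        sides = [arr.flower_distance(i, (i + 1) % 5) for i in range(5)]
        assert sides == pytest.approx([5.0] * 5)

    def test_scaling_scales_distance_table_linearly(self):
        small = regular_polygon(5, 5.0)
        big = regular_polygon(5, 50.0)
        np.testing.assert_allclose(big.distances, 10.0 * small.distances, rtol=1e-12)

    def test_nest_coincident_with_vertex_rejected(self):
        with pytest.raises(ValueError, match="coincident"):
            regular_polygon(3, 1.0, nest_at="vertex")
        # an offset nest near a vertex is fine
        arr = regular_polygon(3, 1.0, nest_at=(0.5, 0.1))
        assert arr.n_flowers == 3

    @pytest.mark.parametrize("n,side", [(2, 1.0), (5, 0.0), (5, -1.0)])
    def test_degenerate_inputs_rejected(self, n, side):
        with pytest.raises(ValueError):
            regular_polygon(n, side)


class TestRandomUniform:
    def test_seed_determinism(self):
        a = random_uniform(10, 25.0, rng_seed=1)
        b = random_uniform(10, 25.0, rng_seed=1)
        np.testing.assert_array_equal(a.flowers, b.flowers)

    def test_single_flower_round_trip_length(self):
        arr = random_uniform(1, 10.0, rng_seed=3)
        assert arr.route_length([0]) == pytest.approx(2.0 * arr.nest_distance(0))

    def test_mean_nearest_neighbour_distance_matches_poisson_form(self):
        # E[NN distance] for intensity n/area is 0.5 / sqrt(n/area) in the
        # unbounded-Poisson limit; at n = 10 in a square the boundary
        # inflates it substantially, so the Donnelly edge correction
        # (+ (0.0514 + 0.041/sqrt(n)) * perimeter / n) is applied before
        # asserting the 5% band.
        n, side = 10, 25.0
        expected = 0.5 / np.sqrt(n / side**2) + (0.0514 + 0.041 / np.sqrt(n)) * (
            4 * side
        ) / n
        means = []
        for seed in range(200):
            arr = random_uniform(n, side, rng_seed=seed)
            d = arr.distances[1:, 1:].copy()
            np.fill_diagonal(d, np.inf)
            means.append(d.min(axis=1).mean())
        assert np.mean(means) == pytest.approx(expected, rel=0.05)

    def test_min_separation_enforced(self):
        arr = random_uniform(20, 1.0, rng_seed=0, min_separation=0.05)
        d = arr.distances.copy()
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 0.05


class TestPatchGrid:
    CENTRES = [(0.0, 0.0), (25.0, 0.0), (25.0, 25.0), (0.0, 25.0)]

    def test_construction_and_membership_partition(self):
        arr = patch_grid(self.CENTRES, 3, 0.5, nest_at=(12.5, 12.5), rng_seed=0)
        assert arr.n_flowers == 12
        assert sorted(set(arr.patch_of)) == [0, 1, 2, 3]
        for p in range(4):
            assert sum(1 for m in arr.patch_of if m == p) == 3

    def test_patch_separation_exceeds_cluster_spread(self):
        arr = patch_grid(self.CENTRES, 3, 0.5, rng_seed=0)
        member = np.asarray(arr.patch_of)
        d = arr.distances[1:, 1:]
        same = member[:, None] == member[None, :]
        intra_max = d[same & (d > 0)].max()
        inter_min = d[~same].min()
        assert inter_min > intra_max

    def test_overlapping_patches_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            patch_grid([(0, 0), (0.5, 0)], 3, 0.5)


class TestPersistence:
    def test_csv_round_trip_is_bit_exact(self, tmp_path):
        arr = random_uniform(7, 25.0, rng_seed=5)
        p = tmp_path / "arr.csv"
        save_array(arr, p)
        back = load_array(p)
        np.testing.assert_array_equal(back.flowers, arr.flowers)
        np.testing.assert_array_equal(back.distances, arr.distances)

    def test_json_and_csv_agree(self, tmp_path):
        arr = regular_polygon(5, 5.0)
        save_array(arr, tmp_path / "a.csv")
        save_array(arr, tmp_path / "a.json")
        a = load_array(tmp_path / "a.csv")
        b = load_array(tmp_path / "a.json")
        np.testing.assert_array_equal(a.flowers, b.flowers)
        np.testing.assert_array_equal(a.nest, b.nest)

    def test_missing_nest_row_is_an_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("label,x,y\nF1,0.0,0.0\nF2,1.0,0.0\n")
        with pytest.raises(ValueError, match="NEST"):
            load_array(p)

    def test_duplicate_labels_rejected(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text("label,x,y\nNEST,0,0\nF1,1.0,0.0\nF1,2.0,0.0\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_array(p)

    def test_non_numeric_coordinates_rejected(self, tmp_path):
        p = tmp_path / "nan.csv"
        p.write_text("label,x,y\nNEST,0,0\nF1,abc,0.0\n")
        with pytest.raises(ValueError, match="non-numeric"):
            load_array(p)

    def test_colocated_pair_survives_csv_round_trip(self, tmp_path):
        arr = FlowerArray(
            nest=(0.0, 0.0),
            flowers=[(1.0, 0.0), (2.0, 1.0), (2.0, 1.0)],
            colocated_pairs=frozenset([frozenset((1, 2))]),
        )
        save_array(arr, tmp_path / "co.csv")
        back = load_array(tmp_path / "co.csv")
        assert back.colocated_pairs == arr.colocated_pairs


class TestInvariants:
    @settings(max_examples=50, deadline=None)
    @given(st.integers(min_value=1, max_value=12), st.integers(min_value=0, max_value=10**6))
    def test_distance_table_symmetric_zero_diagonal(self, n, seed):
        arr = random_uniform(n, 10.0, rng_seed=seed)
        d = arr.distances
        np.testing.assert_array_equal(d, d.T)
        assert np.all(np.diag(d) == 0.0)

    def test_coincident_unflagged_flowers_rejected(self):
        with pytest.raises(ValueError, match="co-located"):
            FlowerArray(nest=(0, 0), flowers=[(1, 1), (1, 1)])

    def test_scaled_preserves_shape(self):
        arr = random_uniform(6, 5.0, rng_seed=2)
        np.testing.assert_allclose(arr.scaled(3.0).distances, 3.0 * arr.distances)


class TestSmallCageArrays:
    @pytest.mark.parametrize("kind", ["positive", "independent", "negative"])
    def test_fixture_loads_with_ten_flowers(self, kind):
        arr = small_cage_array(kind)
        assert arr.n_flowers == 10
        # flight-cage scale: flowers within ~1 m of each other
        assert arr.distances[1:, 1:].max() < 1.2

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            small_cage_array("neutral")
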