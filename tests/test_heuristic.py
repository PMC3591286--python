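"""The traplining heuristic: priors, bout sampling, reinforcement, runs."""

import numpy as np
import pytest

from traplinesim import (
    FlowerArray,
    ModelParams,
    TransitionTable,
    init_transition_table,
    qualifies_for_comparison,
    random_uniform,
    regular_polygon,
    reinforce,
    run_bee,
    run_cohort,
    simulate_bout,
)
from traplinesim.heuristic import Bout


class TestInitTransitionTable:
    def test_equidistant_targets_get_equal_probability(self):
        arr = FlowerArray(nest=(0.0, 0.0), flowers=[(1.0, 0.0), (-1.0, 0.0)])
        tab = init_transition_table(arr, ModelParams())
        assert tab.probs[0, 1] == pytest.approx(0.5)
        assert tab.probs[0, 2] == pytest.approx(0.5)

    def test_pentagon_neighbour_probability_hand_arithmetic(self, pentagon):
        # From any flower: two neighbours at 5 m (w = 1/25 each), two
        # diagonals at 5*phi (w = 1/(5 phi)^2 each), nest at the
        # circumradius (w = (2 sin 36)^2 / 25).  Row-normalised neighbour
        # probability = 0.04 / 0.1658357... = 0.24120...
        phi = (1 + np.sqrt(5)) / 2
        w_side = 1 / 25.0
        w_diag = 1 / (5.0 * phi) ** 2
        w_nest = 1 / (5.0 / (2 * np.sin(np.pi / 5))) ** 2
        expected = w_side / (2 * w_side + 2 * w_diag + w_nest)
        assert expected == pytest.approx(0.24120, abs=1e-5)
        tab = init_transition_table(pentagon, ModelParams())
        assert tab.probs[1, 2] == pytest.approx(expected)

    def test_rows_sum_to_one_with_zero_diagonal(self):
        arr = random_uniform(9, 25.0, rng_seed=8)
        tab = init_transition_table(arr, ModelParams())
        np.testing.assert_allclose(tab.probs.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(np.diag(tab.probs) == 0.0)

    def test_scale_invariance_of_probabilities(self, pentagon):
        t1 = init_transition_table(pentagon, ModelParams())
        t2 = init_transition_table(pentagon.scaled(10.0), ModelParams())
        np.testing.assert_allclose(t1.probs, t2.probs, atol=1e-14)

    def test_colocated_pair_transitions_forbidden(self):
        arr = FlowerArray(
            nest=(0, 0),
            flowers=[(1, 0), (2, 2), (2, 2)],
            colocated_pairs=frozenset([frozenset((1, 2))]),
        )
        tab = init_transition_table(arr, ModelParams())
        assert tab.probs[2, 3] == 0.0 and tab.probs[3, 2] == 0.0
        np.testing.assert_allclose(tab.probs.sum(axis=1), 1.0, atol=1e-12)

    def test_reward_priority_boost_scales_nest_row(self):
        arr = FlowerArray(nest=(0, 0), flowers=[(1, 0), (0, 1)], high_reward=(0,))
        plain = init_transition_table(arr, ModelParams())
        boosted = init_transition_table(arr, ModelParams(reward_priority_boost=3.0))
        # odds of the flagged flower vs the other triple
        odds_plain = plain.probs[0, 1] / plain.probs[0, 2]
        odds_boost = boosted.probs[0, 1] / boosted.probs[0, 2]
        assert odds_boost == pytest.approx(3.0 * odds_plain)


class TestSimulateBout:
    def test_single_flower_forced_path(self, rng):
        arr = random_uniform(1, 10.0, rng_seed=4)
        params = ModelParams().resolve(arr)
        bout = simulate_bout(init_transition_table(arr, params), arr, params, rng)
        assert bout.visits == (0, 1, 0)
        assert bout.length == pytest.approx(2.0 * arr.nest_distance(0))
        assert bout.complete and bout.revisits == 0

    def test_deterministic_cycle_table_reproduces_cycle(self, rng):
        arr = random_uniform(3, 10.0, rng_seed=9)
        params = ModelParams().resolve(arr)
        probs = np.zeros((4, 4))
        for a, b in ((0, 1), (1, 2), (2, 3), (3, 0)):
            probs[a, b] = 1.0
        bout = simulate_bout(TransitionTable(probs), arr, params, rng)
        assert bout.visits == (0, 1, 2, 3, 0)
        assert bout.length == pytest.approx(arr.route_length([0, 1, 2]))

    def test_no_immediate_return_and_no_midbout_nest(self, rng):
        arr = random_uniform(6, 2.0, rng_seed=11)
        params = ModelParams(n_bouts=1).resolve(arr)
        tab = init_transition_table(arr, params)
        for _ in range(200):
            bout = simulate_bout(tab, arr, params, rng)
            assert 0 not in bout.visits[1:-1]
            seq = bout.flower_sequence
            # no self transitions and no immediate A->B->A returns
            assert all(seq[i] != seq[i + 1] for i in range(len(seq) - 1))
            assert all(seq[i] != seq[i + 2] for i in range(len(seq) - 2))

    def test_expected_flower_visits_match_absorbing_chain(self):
        # Independent oracle: enumerate states (here, prev, visited-set) of
        # the masked walk on a 3-flower array and solve the linear system
        # for the expected number of flower visits before the crop fills.
        arr = random_uniform(3, 5.0, rng_seed=21)
        params = ModelParams(rng_seed=0).resolve(arr)
        tab = init_transition_table(arr, params)

        def masked_row(here, prev):
            w = tab.probs[here].copy()
            w[0] = 0.0
            if prev >= 0:
                w[prev] = 0.0
            return w / w.sum()

        # expected additional flower visits from each walk state
        import itertools

        states = []
        for here in (1, 2, 3):
            for prev in (-1, 0, 1, 2, 3):
                if prev == here:
                    continue
                for visited in itertools.chain.from_iterable(
                    itertools.combinations((1, 2, 3), k) for k in (1, 2)
                ):
                    if here not in visited:
                        continue
                    states.append((here, prev, frozenset(visited)))
        index = {s: i for i, s in enumerate(states)}
        A = np.eye(len(states))
        b = np.zeros(len(states))
        for s, i in index.items():
            here, prev, visited = s
            row = masked_row(here, prev)
            for nxt in (1, 2, 3):
                p = row[nxt]
                if p == 0.0:
                    continue
                nvis = visited | {nxt}
                b[i] += p  # one more flower visit
                if len(nvis) < 3:
                    A[i, index[(nxt, here, nvis)]] -= p
        ev = np.linalg.solve(A, b)
        # fold in the first move from the nest
        row0 = masked_row(0, -1)
        expected = 1.0 + sum(
            row0[f] * ev[index[(f, 0, frozenset({f}))]] for f in (1, 2, 3)
        )

        rng = np.random.default_rng(99)
        sims = [simulate_bout(tab, arr, params, rng).n_flower_visits for _ in range(50_000)]
        assert np.mean(sims) == pytest.approx(expected, rel=0.01)


class TestQualification:
    def _bout(self, distinct, complete):
        return Bout(visits=(0, 1, 0), length=1.0, distinct_flowers=distinct,
                    revisits=0, complete=complete)

    def test_full_crop_qualifies(self):
        params = ModelParams(crop_capacity=5)
        assert qualifies_for_comparison(self._bout(5, True), params)

    def test_capped_incomplete_bout_does_not_qualify(self):
        params = ModelParams(crop_capacity=5)
        assert not qualifies_for_comparison(self._bout(3, False), params)

    def test_partial_crop_on_larger_array_qualifies(self):
        params = ModelParams(crop_capacity=4)
        assert qualifies_for_comparison(self._bout(4, True), params)


class TestReinforce:
    def test_hand_arithmetic_row_update(self):
        probs = np.array(
            [
                [0.0, 0.5, 0.3, 0.2],
                [1.0, 0.0, 0.0, 0.0],
                [1.0, 0.0, 0.0, 0.0],
                [1.0, 0.0, 0.0, 0.0],
            ]
        )
        tab = TransitionTable(probs.copy())
        tab.multiply([(0, 2)], 2.0)
        np.testing.assert_allclose(
            tab.probs[0], [0.0, 0.5 / 1.3, 0.6 / 1.3, 0.2 / 1.3], atol=1e-12
        )

    def test_factor_one_is_bitwise_noop(self, pentagon):
        params = ModelParams(enhancement_factor=1.0)
        tab = init_transition_table(pentagon, params)
        before = tab.probs.copy()
        bout = Bout(visits=(0, 1, 2, 3, 4, 5, 0), length=30.0,
                    distinct_flowers=5, revisits=0, complete=True)
        new_best = reinforce(tab, bout, np.inf, params)
        assert new_best == 30.0
        np.testing.assert_array_equal(tab.probs, before)

    def test_longer_bout_leaves_table_unchanged(self, pentagon):
        params = ModelParams(enhancement_factor=2.0)
        tab = init_transition_table(pentagon, params)
        before = tab.probs.copy()
        bout = Bout(visits=(0, 1, 2, 3, 4, 5, 0), length=99.0,
                    distinct_flowers=5, revisits=0, complete=True)
        assert reinforce(tab, bout, 50.0, params) == 50.0
        np.testing.assert_array_equal(tab.probs, before)

    def test_tie_reinforces(self, pentagon):
        params = ModelParams(enhancement_factor=2.0)
        tab = init_transition_table(pentagon, params)
        before = tab.probs.copy()
        bout = Bout(visits=(0, 1, 2, 3, 4, 5, 0), length=50.0,
                    distinct_flowers=5, revisits=0, complete=True)
        assert reinforce(tab, bout, 50.0, params) == 50.0
        assert not np.array_equal(tab.probs, before)

    def test_repeated_reinforcement_converges_to_cycle(self, pentagon):
        params = ModelParams(enhancement_factor=2.0)
        tab = init_transition_table(pentagon, params)
        cycle = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 0)]
        last = np.array([tab.probs[a, b] for a, b in cycle])
        for _ in range(50):
            tab.multiply(cycle, 2.0)
            now = np.array([tab.probs[a, b] for a, b in cycle])
            assert np.all(now >= last - 1e-15)
            assert np.all(now[last < 1.0 - 1e-12] > last[last < 1.0 - 1e-12])
            last = now
        assert np.all(last > 0.999)


class TestRunBee:
    def test_zero_bouts_gives_empty_run(self, pentagon):
        run = run_bee(pentagon, ModelParams(n_bouts=0, rng_seed=0))
        assert run.n_bouts == 0 and run.best_route is None

    def test_l_best_trace_non_increasing(self, pentagon):
        run = run_bee(pentagon, ModelParams(n_bouts=65, rng_seed=5))
        trace = [x for x in run.l_best_trace if np.isfinite(x)]
        assert all(a >= b - 1e-12 for a, b in zip(trace, trace[1:]))

    def test_stability_implies_prior_first_optimal(self, pentagon):
        cohort = run_cohort(pentagon, ModelParams(enhancement_factor=2.0,
                                                  n_bouts=65, rng_seed=17), 50)
        for run in cohort.runs:
            if run.stability_bout is not None:
                assert run.first_optimal_bout is not None
                assert run.stability_bout >= run.first_optimal_bout
            if run.stability_bout is not None:
                assert run.stability_bout_merged is not None
                assert run.stability_bout_merged <= run.stability_bout

    def test_scale_equivariance_full_stack(self):
        arr = random_uniform(6, 25.0, rng_seed=31)
        params = ModelParams(enhancement_factor=2.0, n_bouts=30, rng_seed=7)
        a = run_bee(arr, params, rng=np.random.default_rng(7))
        b = run_bee(arr.scaled(10.0), params, rng=np.random.default_rng(7))
        for ba, bb in zip(a.bouts, b.bouts):
            assert ba.visits == bb.visits
            assert bb.length == pytest.approx(10.0 * ba.length, rel=1e-12)
        assert a.first_optimal_bout == b.first_optimal_bout
        assert a.stability_bout == b.stability_bout
        np.testing.assert_allclose(a.table.probs, b.table.probs, atol=1e-12)

    def test_huge_factor_locks_route(self, pentagon):
        # after one reinforcement at f = 100 the route's per-step
        # probabilities sit near 1, so late bouts overwhelmingly repeat a
        # single modal sequence (occasional one-step excursions remain)
        from collections import Counter

        run = run_bee(pentagon, ModelParams(enhancement_factor=100.0,
                                            n_bouts=65, rng_seed=2))
        late = Counter(b.flower_sequence for b in run.bouts[-20:])
        assert late.most_common(1)[0][1] >= 16

    def test_factor_one_table_unchanged_after_run(self, pentagon):
        params = ModelParams(enhancement_factor=1.0, n_bouts=40, rng_seed=3)
        run = run_bee(pentagon, params)
        init = init_transition_table(pentagon, params.resolve(pentagon))
        np.testing.assert_array_equal(run.table.probs, init.probs)

    def test_row_sums_remain_normalised_after_run(self):
        arr = random_uniform(8, 25.0, rng_seed=13)
        run = run_bee(arr, ModelParams(enhancement_factor=2.0, n_bouts=65, rng_seed=13))
        run.table.validate()


class TestRunCohort:
    def test_single_bee_cohort_equals_single_run(self, pentagon):
        params = ModelParams(enhancement_factor=2.0, n_bouts=20, rng_seed=5)
        cohort = run_cohort(pentagon, params, 1)
        solo = run_bee(
            pentagon, params,
            rng=np.random.default_rng(np.random.SeedSequence(5).spawn(1)[0]),
        )
        assert [b.visits for b in cohort.runs[0].bouts] == [b.visits for b in solo.bouts]

    def test_mean_best_ratio_at_least_one(self, pentagon):
        cohort = run_cohort(pentagon, ModelParams(n_bouts=30, rng_seed=9), 20)
        assert cohort.mean_best_ratio() >= 1.0

    def test_reinforcement_direction_follows_factor(self, pentagon):
        strong = run_cohort(pentagon, ModelParams(enhancement_factor=2.0,
                                                  n_bouts=65, rng_seed=77), 150)
        weak = run_cohort(pentagon, ModelParams(enhancement_factor=1.01,
                                                n_bouts=65, rng_seed=77), 150)
        assert strong.fraction_stable_by(65) > weak.fraction_stable_by(65)
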