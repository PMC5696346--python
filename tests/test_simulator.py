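import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chisquare

from mobisim import (
    FixedLength,
    MemoryParams,
    SpatialDomain,
    TravelerState,
    competition_attractiveness,
    memory_attractiveness,
    simulate_ensemble,
    simulate_trajectory,
    transition_probabilities,
    visited_count_curve,
)

from conftest import brute_force_W


class TestAttractiveness:
    def test_unvisited_is_unity(self):
        state = TravelerState(home=0)
        assert memory_attractiveness(state, 5, MemoryParams(35.0)) == 1.0

    @pytest.mark.parametrize("rank,lam,expected", [(1, 35.0, 36.0), (7, 35.0, 6.0),
                                                   (2, 0.0, 1.0)])
    def test_visited_rank_weight(self, rank, lam, expected):
        order = list(range(rank))
        state = TravelerState(home=0, visit_order=order,
                              visit_counts={j: 1 for j in order})
        assert memory_attractiveness(state, rank - 1, MemoryParams(lam)) == expected

    def test_competition_two_locations(self, two_loc_domain):
        assert competition_attractiveness(two_loc_domain, 0, 1) == pytest.approx(10 / 15)
        assert competition_attractiveness(two_loc_domain, 1, 0) == pytest.approx(5 / 15)

    def test_competition_mutual_nearest_equal_m(self):
        dom = SpatialDomain([0.0, 1.0, 50.0], [0.0] * 3, [6, 6, 6])
        assert competition_attractiveness(dom, 0, 1) == pytest.approx(0.5)
        assert competition_attractiveness(dom, 1, 0) == pytest.approx(0.5)

    def test_self_pair_rejected(self, two_loc_domain):
        with pytest.raises(ValueError):
            competition_attractiveness(two_loc_domain, 1, 1)

    def test_competition_matches_oracle(self, random_domain):
        W = brute_force_W(random_domain)
        for i, j in [(0, 5), (3, 17), (12, 2), (19, 0)]:
            expected = random_domain.m[j] / W[j, i]
            assert competition_attractiveness(random_domain, i, j) == pytest.approx(expected)


class TestTransitionProbabilities:
    def test_symmetric_triangle_fresh_traveler(self, triangle_domain):
        p = transition_probabilities(triangle_domain, TravelerState(home=0),
                                     MemoryParams(0.0))
        np.testing.assert_allclose(p, [0.0, 0.5, 0.5], atol=1e-15)

    def test_lambda_zero_equals_population_only_walk(self, random_domain):
        # with lam=0 the memory factor is 1 everywhere: p = normalized B row
        state = TravelerState(home=4)
        state.record_move(7)
        p = transition_probabilities(random_domain, state, MemoryParams(0.0))
        B = random_domain.competition_matrix()[7].copy()
        np.testing.assert_allclose(p, B / B.sum(), atol=1e-14)

    def test_line_domain_hand_computed_oracle(self, line4_domain):
        # traveler at 2 after visiting 0 then 2; independent enumeration
        state = TravelerState(home=0, visit_order=[0, 2],
                              visit_counts={0: 1, 2: 1}, current=2)
        lam = 2.0
        W = brute_force_W(line4_domain)
        w = np.zeros(4)
        for j in range(4):
            if j == 2:
                continue
            A = {0: 1 + lam / 1, 2: 1 + lam / 2}.get(j, 1.0)
            w[j] = line4_domain.m[j] / W[j, 2] * A
        p = transition_probabilities(line4_domain, state, MemoryParams(lam))
        np.testing.assert_allclose(p, w / w.sum(), atol=1e-14)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_normalization_property(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 15))
        dom = SpatialDomain(rng.uniform(0, 10, n), rng.uniform(0, 10, n),
                            rng.integers(1, 50, n))
        n_visited = int(rng.integers(1, n + 1))
        order = list(rng.permutation(n)[:n_visited])
        state = TravelerState(home=order[0], visit_order=order,
                              visit_counts={j: 1 for j in order},
                              current=order[-1])
        p = transition_probabilities(dom, state, MemoryParams(float(rng.uniform(0, 50))))
        assert abs(p.sum() - 1.0) < 1e-12
        assert p[state.current] == 0.0
        assert np.all(p >= 0)

    def test_monotone_memory_in_lambda(self, random_domain):
        # raising lambda never decreases the rank-1 location's probability
        state = TravelerState(home=3, visit_order=[3, 8, 1],
                              visit_counts={3: 2, 8: 1, 1: 1}, current=1)
        probs = [transition_probabilities(random_domain, state, MemoryParams(lam))[3]
                 for lam in (0.0, 1.0, 5.0, 35.0, 200.0)]
        assert np.all(np.diff(probs) >= 0)


class TestSimulateTrajectory:
    def test_huge_lambda_traps_between_two_locations(self, small_city_domain):
        traj = simulate_trajectory(small_city_domain, home=0, L=100,
                                   params=MemoryParams(1e6), seed=5)
        assert len(set(traj.locations.tolist())) == 2

    def test_deterministic_under_seed(self, small_city_domain):
        a = simulate_trajectory(small_city_domain, 3, 50, MemoryParams(5.0), seed=11)
        b = simulate_trajectory(small_city_domain, 3, 50, MemoryParams(5.0), seed=11)
        np.testing.assert_array_equal(a.locations, b.locations)

    def test_no_consecutive_repeats_and_counting(self, small_city_domain):
        traj = simulate_trajectory(small_city_domain, 2, 200, MemoryParams(10.0), seed=7)
        assert len(traj.locations) == 201
        assert np.all(traj.locations[1:] != traj.locations[:-1])

    def test_invalid_length_rejected(self, small_city_domain):
        with pytest.raises(ValueError):
            simulate_trajectory(small_city_domain, 0, 0, MemoryParams(1.0))

    def test_distinct_count_curve_unit_increments(self, small_city_domain):
        traj = simulate_trajectory(small_city_domain, 1, 300, MemoryParams(2.0), seed=3)
        seen, s = set(), []
        for loc in traj.locations:
            seen.add(int(loc))
            s.append(len(seen))
        assert s[0] == 1
        diffs = np.diff(s)
        assert np.all((diffs == 0) | (diffs == 1))

    def test_lambda_zero_matches_unbiased_walk_exploration(self):
        # uniform populations: distinct-location fraction approximates an
        # unbiased spatial walk's (independent oracle implementation)
        rng = np.random.default_rng(0)
        N = 500
        dom = SpatialDomain(rng.uniform(0, 100, N), rng.uniform(0, 100, N),
                            np.ones(N, dtype=int))
        ens = simulate_ensemble(dom, 20, length_law=FixedLength(500),
                                params=MemoryParams(0.0), seed=2)
        frac_model = visited_count_curve(ens)["S"].iloc[-1] / 500

        oracle_rng = np.random.default_rng(99)
        fracs = []
        for _ in range(20):
            cur = int(oracle_rng.integers(N))
            seen = {cur}
            for _ in range(500):
                nxt = int(oracle_rng.integers(N - 1))
                nxt = nxt + 1 if nxt >= cur else nxt
                seen.add(nxt)
                cur = nxt
            fracs.append(len(seen) / N)
        assert frac_model == pytest.approx(np.mean(fracs), rel=0.05)


class TestSimulateEnsemble:
    def test_single_traveler_reduces_to_trajectory(self, small_city_domain):
        ens = simulate_ensemble(small_city_domain, 1, length_law=FixedLength(20),
                                params=MemoryParams(3.0), seed=8)
        assert len(ens) == 1
        assert ens.trajectories[0].L == 20

    def test_degenerate_length_law(self, small_city_domain):
        ens = simulate_ensemble(small_city_domain, 10, length_law=FixedLength(5),
                                params=MemoryParams(1.0), seed=0)
        assert all(len(t.locations) == 6 for t in ens)

    def test_reproducible_under_seed(self, small_city_domain):
        a = simulate_ensemble(small_city_domain, 5, length_law=FixedLength(30), seed=4)
        b = simulate_ensemble(small_city_domain, 5, length_law=FixedLength(30), seed=4)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.locations, tb.locations)

    def test_home_sampling_proportional_to_population(self):
        dom = SpatialDomain(np.arange(10.0), np.zeros(10),
                            [1, 2, 3, 4, 5, 6, 7, 8, 9, 10])
        ens = simulate_ensemble(dom, 10_000, length_law=FixedLength(1), seed=6)
        counts = np.bincount(ens.homes, minlength=10)
        expected = 10_000 * dom.m / dom.m.sum()
        assert chisquare(counts, expected).pvalue > 1e-3

    def test_explicit_homes_and_length_mismatch(self, small_city_domain):
        with pytest.raises(ValueError):
            simulate_ensemble(small_city_domain, 3, homes=[0, 1], seed=0)
        with pytest.raises(ValueError):
            simulate_ensemble(small_city_domain, 3, length_law=[5, 5], seed=0)
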