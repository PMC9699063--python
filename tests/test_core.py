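"""Core MSC algorithm: simplification, clustering, renormalization, outliers."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_dm
from mscluster import (
    RunParams,
    ShortestDistanceList,
    build_sdl,
    cluster_level,
    detect_outliers,
    lower_median,
    make_distance_matrix,
    renormalize,
    run_msc,
    transform_distances,
)


def groups_as_label_sets(dm, clustering):
    return {frozenset(dm.ids[i] for i in g) for g in clustering.groups}


class TestShortestDistanceList:
    def test_toy_t1(self, toy_t1):
        sdl = build_sdl(toy_t1)
        # C is equidistant (2) from A and B; the tie resolves to the lower index A
        assert list(sdl.nearest) == [1, 0, 0, 4, 3]
        assert list(sdl.nearest_dist) == [1, 1, 2, 1, 1]
        assert sdl.l_med == 1

    def test_two_nodes(self):
        dm = make_distance_matrix([[0, 7], [7, 0]], ["A", "B"])
        sdl = build_sdl(dm)
        assert list(sdl.nearest) == [1, 0]
        assert list(sdl.nearest_dist) == [7, 7]
        assert sdl.l_med == 7

    def test_matches_brute_force_row_minima(self, rng):
        dm = random_dm(rng, 50)
        sdl = build_sdl(dm)
        for i in range(50):
            row = [(dm.data[i, j], j) for j in range(50) if j != i]
            d_min, j_min = min(row)
            assert sdl.nearest_dist[i] == d_min
            assert sdl.nearest[i] == j_min

    def test_rejects_single_node(self):
        with pytest.raises(ValueError, match="at least 2"):
            build_sdl(np.zeros((1, 1)))

    def test_lower_median_convention(self):
        assert lower_median([1, 2, 3, 4]) == 2
        assert lower_median([3, 1, 2]) == 2
        assert lower_median([5]) == 5


class TestDetectOutliers:
    def test_single_far_node(self):
        sdl = build_sdl_from_dists([1, 1, 2, 1, 50])
        assert detect_outliers(sdl, 3) == {4}

    def test_all_equal_never_flagged(self):
        sdl = build_sdl_from_dists([2, 2, 2, 2])
        for m in (1, 3, 100):
            assert detect_outliers(sdl, m) == frozenset()

    def test_lower_median_drives_threshold(self):
        # nearest distances 1,2,3,4 with m=1: L_med = 2 (lower median),
        # so the nodes at 3 and 4 are flagged
        sdl = build_sdl_from_dists([1, 2, 3, 4])
        assert detect_outliers(sdl, 1) == {2, 3}

    def test_invalid_multiplier(self):
        sdl = build_sdl_from_dists([1, 2])
        with pytest.raises(ValueError):
            detect_outliers(sdl, 0)

    def test_infinite_m_disables_detection(self):
        sdl = build_sdl_from_dists([1, 1, 1e12])
        assert detect_outliers(sdl, math.inf) == frozenset()


def build_sdl_from_dists(dists):
    dists = np.asarray(dists, dtype=float)
    nearest = np.zeros(len(dists), dtype=int)
    return ShortestDistanceList(nearest, dists, lower_median(dists))


class TestClusterLevel:
    def test_toy_t1_groups_and_links(self, toy_t1):
        sdl = build_sdl(toy_t1)
        lc = cluster_level(toy_t1, sdl, level=1)
        assert groups_as_label_sets(toy_t1, lc) == {
            frozenset("ABC"), frozenset("DE")
        }
        assert lc.group_ids == ("L1G1", "L1G2")
        assert lc.core_links[0] == (0, 1, 1.0)  # A-B
        assert lc.core_links[1] == (3, 4, 1.0)  # D-E
        assert lc.member_links == {2: (0, 2.0)}  # C joins via A

    def test_two_nodes_single_group(self):
        dm = make_distance_matrix([[0, 7], [7, 0]], ["A", "B"])
        lc = cluster_level(dm, build_sdl(dm))
        assert len(lc.groups) == 1
        assert lc.core_links[0] == (0, 1, 7.0)

    def test_declared_outlier_is_singleton_and_nn_recomputed(self, toy_t1):
        sdl = build_sdl(toy_t1)
        lc = cluster_level(toy_t1, sdl, level=1, outlier_set={2})
        assert groups_as_label_sets(toy_t1, lc) == {
            frozenset("AB"), frozenset("C"), frozenset("DE")
        }
        singleton = lc.groups.index((2,))
        assert lc.core_links[singleton] is None
        assert 2 not in lc.member_links

    def test_matches_brute_force_nn_components(self, rng):
        """Level-1 groups = components of the independently built NN graph."""
        import networkx as nx

        for _ in range(20):
            n = int(rng.integers(4, 40))
            dm = random_dm(rng, n)
            lc = cluster_level(dm, build_sdl(dm))
            g = nx.Graph()
            g.add_nodes_from(range(n))
            for i in range(n):
                row = [(dm.data[i, j], j) for j in range(n) if j != i]
                _, j_min = min(row)
                g.add_edge(i, j_min)
            expected = {frozenset(c) for c in nx.connected_components(g)}
            assert {frozenset(grp) for grp in lc.groups} == expected

    def test_core_links_are_optimal_mutual_pairs(self, rng):
        """Each core link is the minimum-distance mutual-nearest pair of its
        group, verified by exhaustive search."""
        dm = random_dm(rng, 40)
        sdl = build_sdl(dm)
        lc = cluster_level(dm, sdl)
        for members, core in zip(lc.groups, lc.core_links):
            if len(members) < 2:
                assert core is None
                continue
            mutual = [
                (dm.data[i, j], i, j)
                for i in members
                for j in members
                if i < j and sdl.nearest[i] == j and sdl.nearest[j] == i
            ]
            assert (core[2], core[0], core[1]) == min(mutual)


class TestRenormalize:
    def test_toy_t1_collapses_to_cross_distance(self, toy_t1):
        lc = cluster_level(toy_t1, build_sdl(toy_t1))
        rn = renormalize(toy_t1, lc)
        assert rn.shape == (2, 2)
        assert list(rn.ids) == ["L1G1", "L1G2"]
        assert rn.data[0, 1] == 10.0

    def test_all_singletons_is_identity(self, rng):
        from mscluster.core import LevelClustering

        dm = random_dm(rng, 6)
        lc = LevelClustering(
            level=1,
            groups=tuple((i,) for i in range(6)),
            group_ids=tuple(f"L1G{i+1}" for i in range(6)),
            core_links=(None,) * 6,
        )
        rn = renormalize(dm, lc)
        np.testing.assert_array_equal(rn.data, dm.data)

    def test_planted_blocks_yield_between_interval(self, rng):
        from mscluster import PlantedSpec, generate

        res = generate(PlantedSpec(block_sizes=(4, 4, 4), seed=11))
        dm = res.distance_matrix
        lc = cluster_level(dm, build_sdl(dm))
        rn = renormalize(dm, lc)
        assert rn.shape == (3, 3)
        off = rn.data[np.triu_indices(3, k=1)]
        assert np.all((off >= 5.0) & (off <= 6.0))

    def test_entries_are_brute_force_minima(self, rng):
        dm = random_dm(rng, 25)
        lc = cluster_level(dm, build_sdl(dm))
        rn = renormalize(dm, lc)
        for gi, g in enumerate(lc.groups):
            for hi, h in enumerate(lc.groups):
                if gi == hi:
                    continue
                expected = min(dm.data[a, b] for a in g for b in h)
                assert rn.data[gi, hi] == expected


class TestRunMsc:
    def test_toy_t1_two_levels(self, toy_t1):
        h = run_msc(toy_t1, RunParams(m=10, n_limit=1))
        assert h.group_counts == (2, 1)
        assert h.stop_reason == "n_limit"
        assert h.group_id(1, 0) == "L1G1" and h.group_id(1, 3) == "L1G2"
        assert h.group_id(2, 0) == "L2G1"

    def test_two_node_matrix_single_level(self):
        dm = make_distance_matrix([[0, 7], [7, 0]], ["A", "B"])
        h = run_msc(dm, RunParams(n_limit=1))
        assert h.group_counts == (1,)

    def test_planted_four_blocks_recovered_then_merged(self, rng):
        from mscluster import PlantedSpec, generate

        res = generate(PlantedSpec(block_sizes=(10, 10, 10, 10),
                                   level_gaps=((10.0, 11.0),), seed=5))
        h = run_msc(res.distance_matrix, RunParams(m=math.inf, n_limit=2))
        level1 = {frozenset(h.group_elements(1, g)) for g in range(h.group_counts[0])}
        planted = {
            frozenset(lab for lab, grp in res.partitions[0].assignment.items()
                      if grp == g)
            for g in set(res.partitions[0].assignment.values())
        }
        assert level1 == planted
        assert h.group_counts[-1] <= 2

    def test_partitions_are_nested_with_nonincreasing_counts(self, rng):
        for _ in range(10):
            dm = random_dm(rng, int(rng.integers(5, 40)))
            h = run_msc(dm, RunParams(m=3, n_limit=1))
            counts = h.group_counts
            assert all(a >= b for a, b in zip(counts, counts[1:]))
            for lvl in range(h.n_levels - 1):
                coarse = h.membership[lvl + 1]
                fine = h.membership[lvl]
                # every fine group maps into exactly one coarse group
                for g in np.unique(fine):
                    assert len(np.unique(coarse[fine == g])) == 1

    def test_determinism_bit_identical(self, rng):
        dm = random_dm(rng, 30)
        h1 = run_msc(dm, RunParams(m=3, n_limit=2))
        h2 = run_msc(dm, RunParams(m=3, n_limit=2))
        np.testing.assert_array_equal(h1.membership, h2.membership)
        assert h1.summary() == h2.summary()

    def test_fixed_point_reported_not_raised(self):
        # two tight pairs far apart, n_limit=1: after level 2 the two groups
        # cannot merge below n_limit only if detection separates them --
        # instead force a fixed point with an all-outlier level via huge m
        # asymmetry; simplest: a matrix whose clustering reaches 1 group
        # still reports n_limit, so check the fixed_point branch directly
        from mscluster.core import _run_levels

        dm = make_distance_matrix(
            [[0, 1, 9, 9], [1, 0, 9, 9], [9, 9, 0, 1], [9, 9, 1, 0]],
            list("ABCD"),
        )
        # with m tiny every node is an outlier: the partition cannot change
        levels, _, _, reason = _run_levels(dm, RunParams(m=1e-9, n_limit=1), 1)
        assert reason == "fixed_point"
        assert levels[-1].n_groups == 4

    def test_monotone_transform_gives_identical_hierarchy(self, rng):
        """Any strictly increasing rescaling (x^d) of the distances leaves
        the whole hierarchy unchanged, group ids included."""
        params = RunParams(m=math.inf, n_limit=1)
        for d in (0.02, 0.5, 2.0):
            for _ in range(5):
                dm = random_dm(rng, int(rng.integers(5, 30)))
                h1 = run_msc(dm, params)
                h2 = run_msc(transform_distances(dm, d), params)
                assert h1.n_levels == h2.n_levels
                np.testing.assert_array_equal(h1.membership, h2.membership)
                for l1, l2 in zip(h1.levels, h2.levels):
                    assert l1.group_ids == l2.group_ids
                    assert l1.groups == l2.groups

    def test_outlier_pass_only_on_final_levels(self):
        """An element-level outlier is flagged at the final pass, split off
        as a singleton, and the remaining nodes are reclustered without it."""
        from mscluster import PlantedSpec, generate

        res = generate(PlantedSpec(block_sizes=(5, 5), n_outliers=1, seed=2))
        h = run_msc(res.distance_matrix, RunParams(m=3, n_limit=3))
        assert h.outlier_elements(h.n_levels) == {"OUT1"}
        final = {frozenset(h.group_elements(h.n_levels, g))
                 for g in range(h.group_counts[-1])}
        assert frozenset(["OUT1"]) in final

    def test_zero_distance_pairs_co_cluster(self):
        dm = make_distance_matrix(
            [[0, 0, 5], [0, 0, 5], [5, 5, 0]], list("ABC")
        )
        h = run_msc(dm, RunParams(m=math.inf, n_limit=2))
        assert h.group_id(1, 0) == h.group_id(1, 1)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            RunParams(m=-1)
        with pytest.raises(ValueError):
            RunParams(n_limit=0)
        with pytest.raises(ValueError):
            RunParams(max_levels=0)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**31 - 1), n=st.integers(4, 25),
       d=st.sampled_from([0.02, 0.3, 3.0]))
def test_property_power_invariance(seed, n, d):
    """Hierarchies from x and x^d coincide level by level (detection off)."""
    dm = random_dm(np.random.default_rng(seed), n)
    params = RunParams(m=math.inf, n_limit=1)
    h1 = run_msc(dm, params)
    h2 = run_msc(transform_distances(dm, d), params)
    np.testing.assert_array_equal(h1.membership, h2.membership)
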