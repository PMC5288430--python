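"""Network measures: separation sets, exposures, relative distance, Coleman."""

import networkx as nx
import numpy as np
import pytest

from silnet.metrics import (coleman_index, coleman_index_network,
                            exposure_at_degree, household_exposure,
                            relative_distance_to_smokers, separation_sets)


def bfs_separation_sets(net, ego):
    """Independent oracle: distance-k sets by breadth-first search."""
    g = nx.from_numpy_array(np.asarray(net.adjacency, dtype=int),
                            create_using=nx.DiGraph)
    lengths = nx.single_source_shortest_path_length(g, net.index_of(ego))
    out = []
    for k in (1, 2, 3):
        out.append(frozenset(net.roster[v] for v, d in lengths.items() if d == k))
    return tuple(out)


class TestSeparationSets:
    def test_chain(self, network_factory):
        net = network_factory([(0, 1), (1, 2), (2, 3)])
        assert separation_sets(net, "v0") == (
            frozenset({"v1"}), frozenset({"v2"}), frozenset({"v3"}))

    def test_shortcut_keeps_node_in_nearest_set(self, network_factory):
        # a->b, a->c, b->c: c is at distance 1, not again at distance 2
        net = network_factory([(0, 1), (0, 2), (1, 2)])
        s1, s2, s3 = separation_sets(net, "v0")
        assert s1 == frozenset({"v1", "v2"})
        assert s2 == frozenset() and s3 == frozenset()

    def test_isolate_has_empty_sets(self, network_factory):
        net = network_factory([(1, 2)], n=3)
        assert separation_sets(net, "v0") == (frozenset(),) * 3

    def test_walk_variant_keeps_cyclic_reachability(self, network_factory):
        # 2-cycle a<->b: walk variant sees b again at k=3; exact does not
        net = network_factory([(0, 1), (1, 0)])
        assert separation_sets(net, "v0", variant="walk")[2] == frozenset({"v1"})
        assert separation_sets(net, "v0", variant="exact")[2] == frozenset()

    def test_unknown_variant_rejected(self, network_factory):
        with pytest.raises(ValueError):
            separation_sets(network_factory([(0, 1)]), "v0", variant="bogus")

    def test_matrix_powers_match_bfs_oracle_on_random_digraphs(
            self, network_factory):
        rng = np.random.default_rng(7)
        for _ in range(60):
            n = int(rng.integers(2, 40))
            adj = (rng.random((n, n)) < rng.uniform(0.02, 0.3))
            np.fill_diagonal(adj, False)
            net = network_factory(
                [tuple(e) for e in np.argwhere(adj)], n=n)
            ego = f"v{rng.integers(n)}"
            assert separation_sets(net, ego) == bfs_separation_sets(net, ego)


class TestExposure:
    def test_direct_ratio(self, network_factory):
        net = network_factory([(0, 1), (0, 2)], smokers=[1])
        assert exposure_at_degree(net, "v0", 1) == 50.0

    def test_second_degree_smoker(self, network_factory):
        net = network_factory([(0, 1), (1, 2)], smokers=[2])
        assert exposure_at_degree(net, "v0", 2) == 100.0

    def test_no_smoking_friends_is_zero(self, network_factory):
        net = network_factory([(0, 1), (0, 2)], smokers=[])
        assert exposure_at_degree(net, "v0", 1) == 0.0

    def test_empty_set_is_missing(self, network_factory):
        net = network_factory([(0, 1)], n=3)
        assert exposure_at_degree(net, "v0", 2) is None
        assert exposure_at_degree(net, "v2", 1) is None

    def test_bad_degree_rejected(self, network_factory):
        with pytest.raises(ValueError):
            exposure_at_degree(network_factory([(0, 1)]), "v0", 4)

    def test_invariant_under_roster_permutation(self, network_factory):
        rng = np.random.default_rng(3)
        n = 20
        adj = (rng.random((n, n)) < 0.15)
        np.fill_diagonal(adj, False)
        smokers = list(np.flatnonzero(rng.random(n) < 0.3))
        edges = [tuple(e) for e in np.argwhere(adj)]
        net = network_factory(edges, n=n, smokers=smokers)
        perm = rng.permutation(n)
        edges_p = [(int(perm[i]), int(perm[j])) for i, j in edges]
        net_p = network_factory(edges_p, n=n,
                                smokers=[int(perm[s]) for s in smokers])
        for i in range(n):
            for k in (1, 2, 3):
                assert exposure_at_degree(net, f"v{i}", k) == \
                    exposure_at_degree(net_p, f"v{perm[i]}", k)


class TestRelativeDistance:
    def test_worked_four_node_example(self, network_factory):
        # ego->A(smoker), ego->B, B->C: W=(1,1,2), s=1, g=3 -> 75%
        net = network_factory([(0, 1), (0, 2), (2, 3)], smokers=[1])
        assert relative_distance_to_smokers(net, "v0") == pytest.approx(75.0)

    def test_all_smoking_alters_is_exactly_100(self, network_factory):
        net = network_factory([(0, 1), (0, 2), (2, 3)], smokers=[1, 2, 3])
        assert relative_distance_to_smokers(net, "v0") == 100.0

    def test_no_smokers_is_missing(self, network_factory):
        net = network_factory([(0, 1), (1, 2)], smokers=[])
        assert relative_distance_to_smokers(net, "v0") is None

    def test_singleton_network_is_missing(self, network_factory):
        net = network_factory([], n=1)
        assert relative_distance_to_smokers(net, "v0") is None

    def test_unreachable_alter_enters_at_max_finite_distance(
            self, network_factory):
        # chain 0->1->2 plus isolate 3 (smoker): W(0,3) = max finite = 2
        net = network_factory([(0, 1), (1, 2)], n=4, smokers=[3])
        # smoker mean = 2, all-alter mean = (1+2+2)/3 -> 120%
        assert relative_distance_to_smokers(net, "v0") == pytest.approx(120.0)

    def test_moving_smoker_farther_increases_statistic(self, network_factory):
        # smoker adjacent vs smoker at distance 2, same topology
        near = network_factory([(0, 1), (0, 2), (2, 3)], smokers=[1])
        far = network_factory([(0, 1), (0, 2), (2, 3)], smokers=[3])
        assert relative_distance_to_smokers(far, "v0") > \
            relative_distance_to_smokers(near, "v0")

    def test_symmetrized_mode_uses_undirected_geodesics(self, network_factory):
        # 1->0: directed ego distance to 1 is max-finite; symmetrized is 1
        net = network_factory([(1, 0), (0, 2)], smokers=[1])
        directed = relative_distance_to_smokers(net, "v0", mode="directed")
        symmetrized = relative_distance_to_smokers(net, "v0", mode="symmetrized")
        assert symmetrized < directed


class TestColemanIndex:
    def test_all_internal_ties_is_one(self, network_factory):
        groups = ["a"] * 5 + ["b"] * 5
        net = network_factory([(0, 1), (0, 2), (0, 3), (0, 4)], n=10,
                              groups=groups)
        assert coleman_index(net, "v0") == 1.0

    def test_all_external_ties_is_minus_one(self, network_factory):
        groups = ["a"] * 5 + ["b"] * 5
        net = network_factory([(0, 5), (0, 6), (0, 7), (0, 8)], n=10,
                              groups=groups)
        assert coleman_index(net, "v0") == -1.0

    def test_observed_equal_expected_is_zero(self, network_factory):
        # availability (6-1)/(11-1) = 0.5; 2 of 4 ties internal
        groups = ["a"] * 6 + ["b"] * 5
        net = network_factory([(0, 1), (0, 2), (0, 6), (0, 7)], n=11,
                              groups=groups)
        assert coleman_index(net, "v0") == 0.0

    def test_zero_out_degree_is_missing(self, network_factory):
        net = network_factory([(1, 0)], n=4, groups=["a", "a", "b", "b"])
        assert coleman_index(net, "v0") is None

    def test_degenerate_availability_is_missing(self, network_factory):
        net = network_factory([(0, 1), (0, 2)], n=3, groups=["a", "b", "b"])
        assert coleman_index(net, "v0") is None  # singleton group, p = 0
        net2 = network_factory([(0, 1)], n=3, groups=["a", "a", "a"])
        assert coleman_index(net2, "v0") is None  # whole school, p = 1

    def test_unlabeled_alters_rejected(self, network_factory):
        net = network_factory([(0, 1)], n=2, groups=["a", None])
        with pytest.raises(ValueError):
            coleman_index(net, "v0")

    def test_bounded_on_random_graphs(self, network_factory):
        rng = np.random.default_rng(11)
        for _ in range(40):
            n = int(rng.integers(4, 30))
            adj = rng.random((n, n)) < 0.2
            np.fill_diagonal(adj, False)
            groups = rng.choice(["a", "b", "c"], size=n)
            net = network_factory([tuple(e) for e in np.argwhere(adj)], n=n,
                                  groups=list(groups))
            for i in range(n):
                v = coleman_index(net, f"v{i}")
                assert v is None or -1.0 <= v <= 1.0

    def test_network_level_index_pools_group_counts(self, network_factory):
        groups = ["a"] * 3 + ["b"] * 3
        # every a-tie internal, every b-tie external
        net = network_factory([(0, 1), (1, 2), (3, 0), (4, 1)], n=6,
                              groups=groups)
        assert coleman_index_network(net, "a") == 1.0
        assert coleman_index_network(net, "b") == -1.0
        assert coleman_index_network(net) == 0.0  # equal tie weights


class TestHouseholdExposure:
    @pytest.mark.parametrize("count", [0, 3])
    def test_passthrough(self, student_factory, count):
        assert household_exposure(
            student_factory("a", household_smokers=count)) == count

    def test_negative_rejected(self, student_factory):
        rec = student_factory("a")
        rec.household_smokers = -1
        with pytest.raises(ValueError):
            household_exposure(rec)
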