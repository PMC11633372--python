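"""Feedback loops, intervention paths and ripple shells."""

from __future__ import annotations

import pytest

from causalmaps import (
    CausalMap,
    Polarity,
    all_paths,
    classify_loop,
    disjoint_paths,
    enumerate_loops,
    ripple_shells,
)

import oracles
from conftest import random_map

P, N, U = Polarity.POSITIVE, Polarity.NEGATIVE, Polarity.UNSPECIFIED


class TestClassifyLoop:
    @pytest.mark.parametrize(
        "polarities,expected",
        [
            ([P, P], "reinforcing"),
            ([P, N], "balancing"),
            ([P, N, N], "reinforcing"),
            ([N], "balancing"),
            ([N, N, N], "balancing"),
            ([P, U], "undetermined"),
            ([U], "undetermined"),
        ],
    )
    def test_sign_parity(self, polarities, expected):
        assert classify_loop(polarities) == expected

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            classify_loop([])

    @pytest.mark.parametrize("polarities", [[P, N], [N, N, P], [P, U, N]])
    def test_rotation_invariance(self, polarities):
        base = classify_loop(polarities)
        for shift in range(1, len(polarities)):
            rotated = polarities[shift:] + polarities[:shift]
            assert classify_loop(rotated) == base


class TestEnumerateLoops:
    def test_reinforcing_pair(self, fixtures):
        loops, complete = enumerate_loops(fixtures["reinforcing_pair"])
        assert complete and len(loops) == 1
        assert loops[0].classification == "reinforcing"
        assert loops[0].cycle == ["A", "B"]

    def test_balancing_pair(self, fixtures):
        loops, _ = enumerate_loops(fixtures["balancing_pair"])
        assert [l.classification for l in loops] == ["balancing"]

    def test_dag_has_no_loops(self):
        cmap = random_map(seed=4, n=15, p=0.3, acyclic=True)
        loops, complete = enumerate_loops(cmap)
        assert loops == [] and complete

    def test_max_count_truncates_with_flag(self):
        cmap = CausalMap.from_edges(
            [(a, b, "+") for a in "ABCD" for b in "ABCD" if a != b]
        )
        loops, complete = enumerate_loops(cmap, max_length=4, max_count=3)
        assert len(loops) == 3 and not complete

    def test_max_length_bounds_cycles(self):
        cycle5 = CausalMap.from_edges(
            [(f"n{i}", f"n{(i + 1) % 5}", "+") for i in range(5)]
        )
        assert enumerate_loops(cycle5, max_length=4)[0] == []
        assert len(enumerate_loops(cycle5, max_length=5)[0]) == 1

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_dfs_oracle(self, seed):
        cmap = random_map(seed=400 + seed, n=10, p=0.25, p_unspecified=0.2)
        loops, complete = enumerate_loops(cmap, max_length=10)
        assert complete
        assert {tuple(l.cycle) for l in loops} == oracles.simple_cycles_oracle(cmap)
        for loop in loops:
            edge_pols = [
                cmap.polarity(loop.cycle[i], loop.cycle[(i + 1) % len(loop.cycle)])
                for i in range(len(loop.cycle))
            ]
            assert loop.polarities == edge_pols
            assert loop.classification == classify_loop(edge_pols)


class TestDisjointPaths:
    def test_single_edge(self):
        cmap = CausalMap.from_edges([("s", "t", "+")])
        pset = disjoint_paths(cmap, "s", "t")
        assert pset.paths == [["s", "t"]]
        assert pset.net_polarities == ["net-positive"]

    def test_two_parallel_routes(self):
        cmap = CausalMap.from_edges(
            [("s", "a", "+"), ("a", "t", "+"), ("s", "b", "+"), ("b", "t", "-")]
        )
        pset = disjoint_paths(cmap, "s", "t")
        assert len(pset) == 2
        interiors = [set(p[1:-1]) for p in pset.paths]
        assert interiors[0].isdisjoint(interiors[1])
        assert sorted(pset.net_polarities) == ["net-negative", "net-positive"]

    def test_unreachable_target_gives_empty_set(self):
        cmap = CausalMap.from_edges([("t", "s", "+")])
        assert disjoint_paths(cmap, "s", "t").paths == []

    def test_same_endpoint_rejected(self):
        cmap = CausalMap.from_edges([("s", "t", "+")])
        with pytest.raises(ValueError):
            disjoint_paths(cmap, "s", "s")

    @pytest.mark.parametrize("seed", range(10))
    def test_menger_cardinality_on_random_dags(self, seed):
        cmap = random_map(seed=500 + seed, n=12, p=0.25, acyclic=True)
        nodes = cmap.nodes
        source, target = nodes[0], nodes[-1]
        pset = disjoint_paths(cmap, source, target)
        interiors = [set(p[1:-1]) for p in pset.paths]
        for i, a in enumerate(interiors):
            for b in interiors[i + 1:]:
                assert a.isdisjoint(b)
        assert len(pset) == oracles.max_disjoint_paths_oracle(cmap, source, target)

    def test_cardinality_bounded_by_degrees(self):
        cmap = random_map(seed=88, n=15, p=0.3)
        g = cmap.graph
        s, t = cmap.nodes[0], cmap.nodes[-1]
        pset = disjoint_paths(cmap, s, t)
        assert len(pset) <= min(g.out_degree(s), g.in_degree(t))


class TestAllPaths:
    def test_chain_single_positive_path(self, chain3):
        pset = all_paths(chain3, "A", "C")
        assert pset.paths == [["A", "B", "C"]]
        assert pset.net_polarities == ["net-positive"]

    def test_parity_per_path(self):
        cmap = CausalMap.from_edges(
            [("s", "a", "+"), ("a", "t", "-"), ("s", "t", "-")]
        )
        pset = all_paths(cmap, "s", "t")
        assert len(pset) == 2
        assert set(pset.net_polarities) == {"net-negative"}

    def test_unspecified_edge_gives_undetermined(self):
        cmap = CausalMap.from_edges([("s", "a", "+"), ("a", "t", "")])
        assert all_paths(cmap, "s", "t").net_polarities == ["undetermined"]

    def test_truncation_flag(self):
        cmap = CausalMap.from_edges(
            [("s", f"m{i}", "+") for i in range(5)]
            + [(f"m{i}", "t", "+") for i in range(5)]
        )
        pset = all_paths(cmap, "s", "t", max_count=2)
        assert len(pset) == 2 and not pset.complete

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_recursive_enumeration_oracle(self, seed):
        cmap = random_map(seed=600 + seed, n=12, p=0.25, acyclic=True)
        source, target = cmap.nodes[0], cmap.nodes[-1]
        pset = all_paths(cmap, source, target, max_length=11)
        assert pset.complete
        assert {tuple(p) for p in pset.paths} == oracles.simple_paths_oracle(
            cmap, source, target, max_edges=11
        )


class TestRippleShells:
    def test_depth_zero_is_center_only(self, chain3):
        shells = ripple_shells(chain3, "A", 0)
        assert shells.shells == {0: {"A"}}

    def test_chain_layers(self, chain3):
        shells = ripple_shells(chain3, "A", 2)
        assert shells.shells == {0: {"A"}, 1: {"B"}, 2: {"C"}}

    def test_depth_caps_reach(self, chain3):
        assert ripple_shells(chain3, "A", 1).shells == {0: {"A"}, 1: {"B"}}

    def test_unknown_center_rejected(self, chain3):
        with pytest.raises(KeyError):
            ripple_shells(chain3, "zz", 2)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bfs_oracle_and_invariants(self, seed):
        cmap = random_map(seed=700 + seed, n=20, p=0.15)
        center = cmap.nodes[0]
        depth = 4
        shells = ripple_shells(cmap, center, depth)
        dist = oracles.bfs_distances(oracles.adjacency(cmap), center)
        expected = {}
        for node, d in dist.items():
            if d <= depth:
                expected.setdefault(d, set()).add(node)
        assert shells.shells == expected
        # pairwise disjoint, shell 0 is the center
        seen: set[str] = set()
        for d, members in shells.shells.items():
            assert not (members & seen)
            seen |= members
        assert shells.shells[0] == {center}
        # every node at depth d >= 1 has an in-edge from the previous shell
        g = cmap.graph
        for d, members in shells.shells.items():
            if d == 0:
                continue
            for v in members:
                assert any(
                    u in shells.shells[d - 1] for u in g.predecessors(v)
                )

    def test_shell_edges_connect_consecutive_layers(self, fixtures):
        shells = ripple_shells(fixtures["clustering_toy"], "F", 2)
        dist = {v: d for d, vs in shells.shells.items() for v in vs}
        for u, v, _ in shells.shell_edges:
            assert dist[v] in (dist[u], dist[u] + 1)
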