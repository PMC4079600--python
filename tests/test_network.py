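"""Network assembly, centrality and betweenness-ranked group enrichment."""

import itertools
from collections import deque

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from mutpath import (
    RegulatoryEdge,
    build_network,
    compute_centrality,
    group_enrichment,
    node_metrics_table,
    rank_groups,
)
from mutpath.network import read_edges, write_edges


def brute_force_betweenness(g: nx.DiGraph) -> dict:
    """Betweenness by explicit shortest-path enumeration.

    For every ordered pair (s, t), find all shortest paths with BFS and
    credit each intermediate node with its share of pass-throughs.
    """
    btw = {n: 0.0 for n in g.nodes}
    for s, t in itertools.permutations(g.nodes, 2):
        paths = _all_shortest_paths(g, s, t)
        if not paths:
            continue
        for path in paths:
            for node in path[1:-1]:
                btw[node] += 1.0 / len(paths)
    return btw


def _all_shortest_paths(g, s, t):
    # BFS layering, then backtrack every geodesic
    dist = {s: 0}
    parents = {s: []}
    queue = deque([s])
    while queue:
        u = queue.popleft()
        for v in g.successors(u):
            if v not in dist:
                dist[v] = dist[u] + 1
                parents[v] = [u]
                queue.append(v)
            elif dist[v] == dist[u] + 1:
                parents[v].append(u)
    if t not in dist:
        return []
    paths = []

    def backtrack(node, acc):
        if node == s:
            paths.append([s] + acc[::-1])
            return
        for p in parents[node]:
            backtrack(p, acc + [node])

    backtrack(t, [])
    return paths


def edge(s, t, rel="activation"):
    return RegulatoryEdge(s, t, rel, "pw")


class TestBuildNetwork:
    def test_restriction_drops_outside_edges(self):
        net = build_network([edge("A", "B"), edge("A", "C")], {"A", "B"})
        assert net.nodes == {"A", "B"}
        assert net.n_edges == 1

    def test_parallel_edges_collapse_keeping_relations(self):
        net = build_network(
            [edge("A", "B", "activation"), edge("A", "B", "inhibition")], {"A", "B"}
        )
        assert net.n_edges == 1
        assert sorted(net.graph["A"]["B"]["relations"]) == ["activation", "inhibition"]

    def test_self_loops_and_isolated_genes_excluded(self):
        net = build_network([edge("A", "A"), edge("B", "C")], {"A", "B", "C"})
        assert net.nodes == {"B", "C"}

    def test_no_surviving_edges_gives_empty_network(self):
        net = build_network([edge("X", "Y")], {"A"})
        assert net.nodes == set()
        assert net.n_edges == 0


class TestCentrality:
    def test_directed_path_betweenness(self):
        net = build_network([edge("A", "B"), edge("B", "C")], {"A", "B", "C"})
        compute_centrality(net)
        assert net.betweenness == {"A": 0.0, "B": 1.0, "C": 0.0}

    def test_path_interior_positions_hand_computed(self):
        # directed path of n nodes: node at position i (0-based) lies on
        # i * (n - 1 - i) geodesics
        n = 6
        nodes = [f"N{i}" for i in range(n)]
        net = build_network(
            [edge(a, b) for a, b in zip(nodes, nodes[1:])], set(nodes)
        )
        compute_centrality(net)
        for i, node in enumerate(nodes):
            assert net.betweenness[node] == i * (n - 1 - i)
        assert net.betweenness[nodes[0]] == net.betweenness[nodes[-1]] == 0

    def test_triangle_clustering_is_one(self):
        net = build_network(
            [edge("A", "B"), edge("B", "C"), edge("C", "A")], {"A", "B", "C"}
        )
        compute_centrality(net)
        assert net.clustering == {"A": 1.0, "B": 1.0, "C": 1.0}

    def test_dyad_betweenness_zero(self):
        net = build_network([edge("A", "B")], {"A", "B"})
        compute_centrality(net)
        assert set(net.betweenness.values()) == {0.0}

    def test_matches_brute_force_on_random_digraphs(self):
        rng = np.random.default_rng(2024)
        for _ in range(30):
            n = int(rng.integers(4, 12))
            g = nx.gnp_random_graph(n, 0.3, seed=int(rng.integers(2**31)), directed=True)
            mapping = {i: f"G{i}" for i in g.nodes}
            g = nx.relabel_nodes(g, mapping)
            edges = [edge(s, t) for s, t in g.edges]
            net = build_network(edges, set(mapping.values()))
            compute_centrality(net)
            expected = brute_force_betweenness(net.graph)
            for node, val in net.betweenness.items():
                assert val == pytest.approx(expected[node], abs=1e-9)


class TestRankGroups:
    def _star_network(self):
        # hub H sits on every path between leaves
        edges = [edge(f"L{i}", "H") for i in range(3)] + [
            edge("H", f"M{i}") for i in range(3)
        ]
        net = build_network(edges, {f"L{i}" for i in range(3)} | {"H"} | {f"M{i}" for i in range(3)})
        return compute_centrality(net)

    def test_controls_are_zero_betweenness(self):
        net = self._star_network()
        groups = rank_groups(net, ks=[2, 5])
        assert "H" in groups.groups[2]
        assert groups.controls == net.nodes - {"H"}
        assert not groups.controls & set(groups.groups[5])

    def test_groups_truncate_and_nest(self):
        net = self._star_network()
        groups = rank_groups(net, ks=[1, 50])
        assert groups.groups[50] == ["H"]  # only one nonzero-betweenness gene
        assert set(groups.groups[1]) <= set(groups.groups[50])

    def test_all_zero_betweenness(self):
        net = build_network([edge("A", "B")], {"A", "B"})
        compute_centrality(net)
        groups = rank_groups(net, ks=[5])
        assert groups.groups[5] == []
        assert groups.controls == {"A", "B"}

    def test_deterministic_ordering(self):
        net = self._star_network()
        g1 = rank_groups(net)
        g2 = rank_groups(net)
        assert g1.groups == g2.groups

    def test_unsorted_ks_rejected(self):
        net = self._star_network()
        with pytest.raises(ValueError):
            rank_groups(net, ks=[100, 50])


class TestGroupEnrichment:
    def _annotations(self, genes, cancer=(), damaging=(), cons=None):
        return pd.DataFrame(
            {
                "is_known_cancer": [g in cancer for g in genes],
                "is_damaging": [g in damaging for g in genes],
                "conservation": [
                    (cons or {}).get(g, np.nan) for g in genes
                ],
            },
            index=pd.Index(genes, name="gene"),
        )

    def test_identical_composition_gives_p_one(self):
        net = TestRankGroups()._star_network()
        groups = rank_groups(net, ks=[1])
        genes = sorted(net.nodes)
        # half of each side flagged -> no contrast
        ann = self._annotations(genes, cancer=set(genes[::2]), damaging=set(genes[::2]))
        table = group_enrichment(groups, ann)
        assert (table["cancer_p"] >= 0.5).all()

    def test_hub_coupled_annotation_is_detected(self, small_dataset):
        from mutpath import annotate_genes, filter_functional

        records = filter_functional(
            [r for recs in small_dataset.cohorts.values() for r in recs]
        )
        mutated = small_dataset.profile.mutated_genes()
        net = build_network(small_dataset.edges, mutated)
        compute_centrality(net)
        groups = rank_groups(net, ks=[50])
        ann = annotate_genes(
            sorted(net.nodes), records, small_dataset.truth.cancer_genes
        )
        table = group_enrichment(groups, ann.loc[sorted(net.nodes)])
        # driver-biased hubs carry elevated conservation scores
        assert table.loc[0, "conservation_p"] < 0.05

    def test_empty_controls_is_error(self):
        net = build_network([edge("A", "B"), edge("B", "C")], {"A", "B", "C"})
        compute_centrality(net)
        groups = rank_groups(net, ks=[5])
        groups.controls = set()
        with pytest.raises(ValueError, match="control"):
            group_enrichment(groups, self._annotations(["A", "B", "C"]))


class TestEdgeIO:
    def test_roundtrip(self, tmp_path):
        edges = [edge("A", "B", "phosphorylation"), edge("B", "C", "inhibition")]
        path = tmp_path / "edges.tsv"
        write_edges(edges, path)
        assert read_edges(path) == edges

    def test_unknown_relation_maps_to_other(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("source\ttarget\trelation\tpathway_id\nA\tB\tbinding\tpw\n")
        (e,) = read_edges(path)
        assert e.relation == "other"


def test_node_metrics_table_ranks_and_flags():
    edges = [edge("A", "B"), edge("B", "C")]
    net = build_network(edges, {"A", "B", "C"})
    compute_centrality(net)
    groups = rank_groups(net, ks=[1])
    df = node_metrics_table(net, groups)
    assert df.iloc[0]["gene"] == "B"
    assert df.iloc[0]["rank"] == 1
    assert not df.iloc[0]["is_control"]
    assert df[df["gene"] != "B"]["is_control"].all()
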