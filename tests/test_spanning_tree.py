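"""Proximity graph, MST, path scoring, and tabu refinement vs brute force."""

from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from catrace import (
    PointGraph,
    TabuParams,
    build_graph,
    longest_path,
    minimum_spanning_tree,
    tabu_refine,
    top_k_path_lengths,
    tree_score,
)
from catrace.spanning_tree import SpanningTree


# ---------------------------------------------------------------------------
# independent oracles

def spanning_trees_brute_force(n_nodes, edges):
    """All spanning trees of a graph by subset enumeration (union-find)."""
    for subset in combinations(edges, n_nodes - 1):
        parent = list(range(n_nodes))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        ok = True
        for i, j, _ in subset:
            ri, rj = find(i), find(j)
            if ri == rj:
                ok = False
                break
            parent[ri] = rj
        if ok:
            yield subset


def leaf_pair_path_lengths_brute_force(tree_edges):
    """Lengths of every leaf-to-leaf path by explicit path walking."""
    g = nx.Graph()
    g.add_weighted_edges_from(tree_edges)
    leaves = [n for n in g.nodes if g.degree(n) == 1]
    out = []
    for a, b in combinations(leaves, 2):
        path = nx.shortest_path(g, a, b)  # unique in a tree
        out.append(sum(g[u][v]["weight"] for u, v in zip(path, path[1:])))
    return sorted(out, reverse=True)


def random_connected_graph(rng, n):
    """Random weighted connected graph on n nodes."""
    while True:
        positions = rng.uniform(0, 10, size=(n, 3))
        edges = []
        for i, j in combinations(range(n), 2):
            if rng.random() < 0.45:
                edges.append((i, j, float(np.linalg.norm(positions[i] - positions[j]))))
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_weighted_edges_from(edges)
        if nx.is_connected(g):
            return PointGraph(positions, edges)


def random_tree(rng, n):
    """Uniform random labeled tree via a Prüfer sequence, random weights."""
    if n == 2:
        prufer = []
    else:
        prufer = list(rng.integers(0, n, size=n - 2))
    tree = nx.from_prufer_sequence(prufer)
    return [
        (min(i, j), max(i, j), float(rng.uniform(0.5, 5.0)))
        for i, j in tree.edges
    ]


# ---------------------------------------------------------------------------

class TestBuildGraph:
    positions = np.array([[0.0, 0, 0], [2.0, 0, 0], [4.0, 0, 0]])

    def test_collinear_cutoff_3(self):
        g = build_graph(self.positions, edge_cutoff=3.0)
        assert len(g.edges) == 2

    def test_collinear_cutoff_5(self):
        g = build_graph(self.positions, edge_cutoff=5.0)
        assert len(g.edges) == 3

    def test_matches_brute_force_pair_scan(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 10, size=(20, 3))
        cutoff = 4.0
        g = build_graph(pts, edge_cutoff=cutoff)
        expected = {
            (i, j)
            for i, j in combinations(range(20), 2)
            if np.linalg.norm(pts[i] - pts[j]) <= cutoff
        }
        assert {(i, j) for i, j, _ in g.edges} == expected
        for i, j, w in g.edges:
            assert w == pytest.approx(np.linalg.norm(pts[i] - pts[j]))

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ValueError):
            build_graph(np.zeros((1, 3)))


class TestMst:
    def test_triangle_drops_longest_edge(self):
        pos = np.array([[0.0, 0, 0], [1.0, 0, 0], [0.5, 0.9, 0]])
        g = build_graph(pos, edge_cutoff=2.0)
        mst = minimum_spanning_tree(g)
        kept = {(i, j) for i, j, _ in mst.tree_edges}
        assert (0, 1) in kept  # the two shorter sides stay
        assert len(kept) == 2

    def test_tree_input_returned_unchanged(self):
        rng = np.random.default_rng(6)
        edges = random_tree(rng, 8)
        pg = PointGraph(np.zeros((8, 3)), edges)
        mst = minimum_spanning_tree(pg)
        assert sorted(mst.tree_edges) == sorted(edges)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(3, 8))
            pg = random_connected_graph(rng, n)
            mst = minimum_spanning_tree(pg)
            got = sum(w for _, _, w in mst.tree_edges)
            best = min(
                sum(w for _, _, w in subset)
                for subset in spanning_trees_brute_force(n, pg.edges)
            )
            assert got == pytest.approx(best, abs=1e-9)

    def test_operates_on_largest_component(self):
        # two components: a 3-node cluster and a 2-node cluster
        pos = np.array(
            [[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [50.0, 0, 0], [51.0, 0, 0]]
        )
        g = build_graph(pos, edge_cutoff=2.5)
        mst = minimum_spanning_tree(g)
        assert set(mst.nodes) == {0, 1, 2}


class TestTopKPaths:
    def test_path_graph(self):
        t = SpanningTree(PointGraph(np.zeros((3, 3)), []), [(0, 1, 1.0), (1, 2, 2.0)])
        np.testing.assert_allclose(top_k_path_lengths(t, 1), [3.0])

    def test_star_symmetry(self):
        t = SpanningTree(
            PointGraph(np.zeros((4, 3)), []),
            [(0, 1, 1.0), (0, 2, 1.0), (0, 3, 1.0)],
        )
        np.testing.assert_allclose(top_k_path_lengths(t, 2), [2.0, 2.0])

    def test_matches_exhaustive_leaf_pair_enumeration(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            n = int(rng.integers(2, 21))
            edges = random_tree(rng, n)
            t = SpanningTree(PointGraph(np.zeros((n, 3)), edges), edges)
            k = int(rng.integers(1, 8))
            expected = leaf_pair_path_lengths_brute_force(edges)[:k]
            np.testing.assert_allclose(top_k_path_lengths(t, k), expected, atol=1e-9)


class TestLongestPath:
    def test_path_graph_whole_path(self):
        t = SpanningTree(
            PointGraph(np.zeros((4, 3)), []),
            [(0, 1, 1.0), (1, 2, 1.0), (2, 3, 1.0)],
        )
        assert longest_path(t) in ([0, 1, 2, 3], [3, 2, 1, 0])

    def test_star_picks_two_longest_arms(self):
        t = SpanningTree(
            PointGraph(np.zeros((4, 3)), []),
            [(0, 1, 1.0), (0, 2, 2.0), (0, 3, 3.0)],
        )
        p = longest_path(t)
        assert set(p) == {2, 0, 3}

    def test_agrees_with_top1_length(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            n = int(rng.integers(3, 15))
            edges = random_tree(rng, n)
            t = SpanningTree(PointGraph(np.zeros((n, 3)), edges), edges)
            p = longest_path(t)
            g = nx.Graph()
            g.add_weighted_edges_from(edges)
            plen = sum(g[u][v]["weight"] for u, v in zip(p, p[1:]))
            assert plen == pytest.approx(top_k_path_lengths(t, 1)[0], abs=1e-9)


class TestTabuRefine:
    def test_zero_iterations_identity(self):
        rng = np.random.default_rng(10)
        pg = random_connected_graph(rng, 6)
        mst = minimum_spanning_tree(pg)
        out = tabu_refine(mst, TabuParams(n_iterations=0))
        assert sorted(out.tree_edges) == sorted(mst.tree_edges)

    def test_tree_parent_graph_is_noop(self):
        rng = np.random.default_rng(11)
        edges = random_tree(rng, 6)
        pg = PointGraph(np.zeros((6, 3)), edges)
        mst = minimum_spanning_tree(pg)
        out = tabu_refine(mst, TabuParams(n_iterations=20))
        assert sorted(out.tree_edges) == sorted(mst.tree_edges)

    def test_reaches_exhaustive_optimum_on_small_graphs(self):
        rng = np.random.default_rng(12)
        k = 3
        for _ in range(10):
            n = int(rng.integers(4, 8))
            pg = random_connected_graph(rng, n)
            mst = minimum_spanning_tree(pg)
            out = tabu_refine(
                mst, TabuParams(n_iterations=150, tabu_tenure=5, top_k_paths=k,
                                rng_seed=0)
            )
            best = max(
                tree_score(SpanningTree(pg, list(subset)), k)
                for subset in spanning_trees_brute_force(n, pg.edges)
            )
            assert out.score == pytest.approx(best, abs=1e-9)

    def test_result_never_below_input_mst(self):
        rng = np.random.default_rng(13)
        for _ in range(5):
            pg = random_connected_graph(rng, 7)
            mst = minimum_spanning_tree(pg)
            out = tabu_refine(mst, TabuParams(n_iterations=20, top_k_paths=4))
            assert out.score >= tree_score(mst, 4) - 1e-9

    def test_output_is_spanning_tree_of_same_component(self):
        rng = np.random.default_rng(14)
        pg = random_connected_graph(rng, 7)
        mst = minimum_spanning_tree(pg)
        out = tabu_refine(mst, TabuParams(n_iterations=30, top_k_paths=4))
        g = out.to_networkx()
        assert nx.is_tree(g)
        assert set(g.nodes) == set(mst.nodes)
        parent = {(i, j) for i, j, _ in pg.edges}
        assert all((i, j) in parent for i, j, _ in out.tree_edges)

    def test_reproducible_with_fixed_seed(self):
        rng = np.random.default_rng(15)
        pg = random_connected_graph(rng, 7)
        mst = minimum_spanning_tree(pg)
        p = TabuParams(n_iterations=25, top_k_paths=3, rng_seed=42, move_budget=5)
        a = tabu_refine(mst, p)
        b = tabu_refine(mst, p)
        assert a.tree_edges == b.tree_edges
        assert a.score == b.score
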