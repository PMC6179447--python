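"""Tree skeletonization of the LDP cloud and tabu-search refinement.

LDPs within an edge cutoff of one another form a proximity graph whose
minimum spanning tree covers the protein main chain surprisingly well —
the point cloud is dense enough that consecutive backbone positions are
near neighbors. The MST is then refined by tabu search: each iteration
deletes one tree edge (splitting the tree) and re-adds the parent-graph
edge across the cut that maximizes the tree score, applying the best
candidate move even when it is worse than the current tree, while a
FIFO tabu list of recently touched edges blocks immediate reversals
(with the usual aspiration exception for moves that beat the global
best). The score of a tree is the summed length of its top-K longest
leaf-to-leaf paths (K = 100 by default): long unbranched paths are what
a single protein chain should look like.

Edge weights are plain Euclidean distances by default; an optional
density-weighted variant divides each length by the mean interpolated
map density along the edge, favouring edges that run through solid
density. Ties are broken by lexicographic node-index order everywhere,
so a fixed RNG seed reproduces a refinement run bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .map_io import DensityGrid, interpolate_density
from .mean_shift import LocalDensePoint

__all__ = [
    "PointGraph",
    "SpanningTree",
    "TabuParams",
    "build_graph",
    "minimum_spanning_tree",
    "top_k_path_lengths",
    "tree_score",
    "longest_path",
    "tabu_refine",
]

DEFAULT_EDGE_CUTOFF = 5.0  # Å, just above the 3.8 Å Cα–Cα spacing
DEFAULT_TOP_K = 100


@dataclass
class PointGraph:
    """Undirected proximity graph over LDP positions.

    ``edges`` holds (i, j, weight) with i < j; weights are Euclidean
    distances in Å (optionally density-weighted, see build_graph).
    """

    positions: np.ndarray  # (n, 3) world Å
    edges: list[tuple[int, int, float]]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.positions)))
        g.add_weighted_edges_from(self.edges)
        return g

    @property
    def n_nodes(self) -> int:
        return len(self.positions)


@dataclass
class SpanningTree:
    """A spanning tree of the largest component of its parent graph."""

    graph: PointGraph
    tree_edges: list[tuple[int, int, float]]
    score: float = 0.0

    @property
    def nodes(self) -> list[int]:
        seen: set[int] = set()
        for i, j, _ in self.tree_edges:
            seen.add(i)
            seen.add(j)
        return sorted(seen)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_weighted_edges_from(self.tree_edges)
        return g


@dataclass(frozen=True)
class TabuParams:
    n_iterations: int = 100
    tabu_tenure: int = 20
    top_k_paths: int = DEFAULT_TOP_K
    rng_seed: int = 0
    move_budget: int = 500  # candidate moves evaluated per iteration

    def __post_init__(self) -> None:
        if self.n_iterations < 0 or self.tabu_tenure <= 0 or self.top_k_paths <= 0:
            raise ValueError("tabu parameters must be positive")


def build_graph(
    ldps: Sequence[LocalDensePoint] | np.ndarray,
    edge_cutoff: float = DEFAULT_EDGE_CUTOFF,
    grid: DensityGrid | None = None,
    density_weighted: bool = False,
) -> PointGraph:
    """Connect all LDP pairs within ``edge_cutoff`` Å.

    With ``density_weighted`` (and a grid), each Euclidean length is
    divided by the mean interpolated density at 5 points along the edge,
    clipped below at 10% of the contour level so weights stay finite.
    """
    if isinstance(ldps, np.ndarray):
        positions = np.atleast_2d(np.asarray(ldps, dtype=float))
    else:
        positions = np.stack([p.position for p in ldps])
    if len(positions) < 2:
        raise ValueError("need at least 2 LDPs to build a graph")
    tree = cKDTree(positions)
    pairs = tree.query_pairs(edge_cutoff, output_type="ndarray")
    edges: list[tuple[int, int, float]] = []
    for i, j in sorted(map(tuple, pairs)):
        w = float(np.linalg.norm(positions[i] - positions[j]))
        if density_weighted:
            if grid is None:
                raise ValueError("density weighting requires a grid")
            ts = np.linspace(0.0, 1.0, 5)[:, None]
            samples = positions[i] * (1 - ts) + positions[j] * ts
            dens = np.asarray(interpolate_density(grid, samples), dtype=float)
            floor = 0.1 * grid.contour_level if grid.contour_level > 0 else 1e-6
            w = w / max(float(dens.mean()), floor)
        edges.append((int(i), int(j), w))
    return PointGraph(positions, edges)


def _largest_component(g: nx.Graph) -> set[int]:
    return max(nx.connected_components(g), key=lambda c: (len(c), -min(c)))


def minimum_spanning_tree(graph: PointGraph) -> SpanningTree:
    """Kruskal MST of the graph's largest connected component.

    Edges are considered in (weight, i, j) order, which fixes the tree
    deterministically even when weights tie.
    """
    g = graph.to_networkx()
    comp = _largest_component(g)
    if len(comp) < 2:
        raise ValueError("largest connected component has fewer than 2 nodes")
    sub = g.subgraph(comp)
    ordered = sorted(sub.edges(data="weight"), key=lambda e: (e[2], e[0], e[1]))
    uf = nx.utils.UnionFind(comp)
    tree_edges: list[tuple[int, int, float]] = []
    for i, j, w in ordered:
        if uf[i] != uf[j]:
            uf.union(i, j)
            tree_edges.append((min(i, j), max(i, j), float(w)))
    st = SpanningTree(graph, tree_edges)
    st.score = tree_score(st)
    return st


def _leaf_path_lengths(tree: SpanningTree) -> np.ndarray:
    """Lengths of the unique simple path between every pair of leaves."""
    g = tree.to_networkx()
    if g.number_of_nodes() < 2:
        return np.zeros(0)
    leaves = sorted(n for n in g.nodes if g.degree(n) == 1)
    lengths = []
    for a_idx, a in enumerate(leaves):
        dist = nx.single_source_dijkstra_path_length(g, a, weight="weight")
        for b in leaves[a_idx + 1:]:
            lengths.append(dist[b])
    return np.asarray(lengths)


def top_k_path_lengths(tree: SpanningTree, k: int = DEFAULT_TOP_K) -> np.ndarray:
    """The k largest leaf-to-leaf path lengths (all, if fewer), descending.

    Any simple path in a tree extends to a leaf-to-leaf path of at least
    its length, so leaf pairs dominate the top of the ranking.
    """
    lengths = _leaf_path_lengths(tree)
    lengths = np.sort(lengths)[::-1]
    return lengths[:k]


def tree_score(tree: SpanningTree, k: int = DEFAULT_TOP_K) -> float:
    return float(np.sum(top_k_path_lengths(tree, k)))


def longest_path(tree: SpanningTree) -> list[int]:
    """The weighted-diameter path of the tree as an ordered node list.

    Ties are broken toward the lexicographically smallest (sorted)
    endpoint pair.
    """
    g = tree.to_networkx()
    nodes = sorted(g.nodes)
    if len(nodes) < 2:
        raise ValueError("tree must have at least 2 nodes")
    leaves = sorted(n for n in g.nodes if g.degree(n) == 1)
    best: tuple[float, tuple[int, int]] | None = None
    for a_idx, a in enumerate(leaves):
        dist = nx.single_source_dijkstra_path_length(g, a, weight="weight")
        for b in leaves[a_idx + 1:]:
            key = (dist[b], (-a, -b))
            if best is None or key[0] > best[0] + 1e-12 or (
                abs(key[0] - best[0]) <= 1e-12 and key[1] > best[1]
            ):
                best = (key[0], key[1])
                ends = (a, b)
    return nx.shortest_path(g, ends[0], ends[1], weight="weight")


def _edge_key(i: int, j: int) -> tuple[int, int]:
    return (i, j) if i < j else (j, i)


def tabu_refine(tree: SpanningTree, params: TabuParams | None = None) -> SpanningTree:
    """Refine a spanning tree by tabu search on the top-K path objective.

    Returns the best-scoring tree ever visited. With no non-tree parent
    edges (or zero iterations) the input is returned unchanged. The
    search is reproducible bit-for-bit for a fixed ``rng_seed``.
    """
    if params is None:
        params = TabuParams()
    graph = tree.graph
    comp_nodes = set(tree.nodes)
    parent_edges = {
        _edge_key(i, j): w
        for i, j, w in graph.edges
        if i in comp_nodes and j in comp_nodes
    }
    current = {_edge_key(i, j): w for i, j, w in tree.tree_edges}
    non_tree = sorted(set(parent_edges) - set(current))
    if not non_tree or params.n_iterations == 0:
        out = replace(tree)
        out.score = tree_score(tree, params.top_k_paths)
        return out

    rng = np.random.default_rng(params.rng_seed)
    k = params.top_k_paths

    def score_of(edge_set: dict[tuple[int, int], float]) -> float:
        st = SpanningTree(graph, [(i, j, w) for (i, j), w in sorted(edge_set.items())])
        return tree_score(st, k)

    best_edges = dict(current)
    best_score = score_of(current)
    cur_score = best_score
    tabu: list[tuple[int, int]] = []

    for _ in range(params.n_iterations):
        g = nx.Graph()
        g.add_weighted_edges_from((i, j, w) for (i, j), w in current.items())

        # candidate (delete, add) pairs: add-edge must reconnect the cut
        candidates: list[tuple[tuple[int, int], tuple[int, int]]] = []
        for del_edge in sorted(current):
            g.remove_edge(*del_edge)
            side = nx.node_connected_component(g, del_edge[0])
            for add_edge in sorted(set(parent_edges) - set(current)):
                if add_edge == del_edge:
                    continue
                if (add_edge[0] in side) != (add_edge[1] in side):
                    candidates.append((del_edge, add_edge))
            g.add_edge(*del_edge, weight=current[del_edge])
        if not candidates:
            break
        if len(candidates) > params.move_budget:
            pick = rng.choice(len(candidates), size=params.move_budget, replace=False)
            candidates = [candidates[p] for p in sorted(pick)]

        best_move = None
        best_move_score = -np.inf
        for del_edge, add_edge in candidates:
            is_tabu = del_edge in tabu or add_edge in tabu
            trial = dict(current)
            del trial[del_edge]
            trial[add_edge] = parent_edges[add_edge]
            s = score_of(trial)
            if is_tabu and s <= best_score:  # aspiration: tabu ok if new global best
                continue
            if s > best_move_score:
                best_move_score = s
                best_move = (del_edge, add_edge)
        if best_move is None:
            continue  # everything tabu and nothing aspires; skip this iteration

        del_edge, add_edge = best_move
        del current[del_edge]
        current[add_edge] = parent_edges[add_edge]
        cur_score = best_move_score
        tabu.extend([del_edge, add_edge])
        while len(tabu) > 2 * params.tabu_tenure:
            tabu.pop(0)
        if cur_score > best_score:
            best_score = cur_score
            best_edges = dict(current)

    out = SpanningTree(
        graph, [(i, j, w) for (i, j), w in sorted(best_edges.items())]
    )
    out.score = best_score
    return out
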