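"""Structural graph features and the graph-distance statistics Θ.

The differential-network test compares two co-expression graphs over the
same gene set through a nonnegative distance Θ that is zero when the graphs
coincide.  Seven statistics are available: the Jensen-Shannon divergence
between spectral densities (the default) or between degree distributions,
Euclidean distances between node centralities or clustering coefficients
(adjusted for the gene-set size), and absolute differences between average
shortest path lengths or spectral entropies.

Node-level scores (degree/strength, eigenvector centrality, betweenness,
closeness, local clustering) double as gene-importance rankings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .coexpression import CoExpressionGraph
from .spectral import (
    BandwidthCriterion,
    SpectralDensity,
    Spectrum,
    adjacency_spectrum,
    density_pair,
    js_divergence,
    spectral_density,
    spectral_entropy,
)

__all__ = [
    "NodeScores",
    "GeneSetProperties",
    "GRAPH_DISTANCE_KINDS",
    "degree_centrality",
    "eigenvector_centrality",
    "path_centrality",
    "local_clustering",
    "average_shortest_path",
    "degree_distribution",
    "graph_distance",
    "adjacency_distance",
    "set_properties",
]

ScoreKind = Literal["degree", "eigenvector", "betweenness", "closeness", "clustering"]
GraphDistanceKind = Literal[
    "spectral_js",
    "degree_dist_js",
    "degree_centrality_dist",
    "eigenvector_centrality_dist",
    "clustering_dist",
    "shortest_path_absdiff",
    "entropy_absdiff",
]

GRAPH_DISTANCE_KINDS: tuple[str, ...] = (
    "spectral_js",
    "degree_dist_js",
    "degree_centrality_dist",
    "eigenvector_centrality_dist",
    "clustering_dist",
    "shortest_path_absdiff",
    "entropy_absdiff",
)


@dataclass(frozen=True)
class NodeScores:
    """A per-gene score vector aligned to the graph's node order."""

    nodes: tuple[str, ...]
    values: np.ndarray
    kind: ScoreKind

    def as_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(self.nodes, self.values)}


@dataclass(frozen=True)
class GeneSetProperties:
    """Summary structural properties of one phenotype's gene-set network."""

    average_degree: float
    average_eigenvector: float
    average_clustering: float
    spectral_entropy: float
    average_shortest_path: float


# ---------------------------------------------------------------------------
# Node scores
# ---------------------------------------------------------------------------

def degree_centrality(graph: CoExpressionGraph) -> NodeScores:
    """Node strength: row sums of the adjacency (edge counts if unweighted)."""
    return NodeScores(tuple(graph.nodes), graph.adjacency.sum(axis=1), "degree")


def eigenvector_centrality(graph: CoExpressionGraph) -> NodeScores:
    """Principal (Perron) eigenvector of the adjacency, nonnegative, unit L2."""
    A = graph.adjacency
    if not A.any():
        raise ValueError("eigenvector centrality undefined for an edgeless graph")
    w, v = np.linalg.eigh(A)
    vec = v[:, -1]
    # Perron vector of a nonnegative matrix has a constant sign; tiny
    # opposite-sign entries are eigensolver round-off.
    vec = np.abs(vec)
    vec /= np.linalg.norm(vec)
    return NodeScores(tuple(graph.nodes), vec, "eigenvector")


def _to_networkx(graph: CoExpressionGraph) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(range(graph.n_vertices))
    n = graph.n_vertices
    iu = np.triu_indices(n, k=1)
    for i, j in zip(*iu):
        w = graph.adjacency[i, j]
        if w > 0:
            G.add_edge(int(i), int(j), weight=float(w))
    return G


def path_centrality(graph: CoExpressionGraph, kind: Literal["betweenness", "closeness"]) -> NodeScores:
    """Shortest-path betweenness or closeness; unweighted graphs only.

    Betweenness is the unnormalized count of shortest-path pairs through a
    node; closeness is (reachable - 1) / sum of distances, computed within
    each connected component.
    """
    if not graph.is_unweighted:
        raise ValueError(f"{kind} centrality requires an unweighted graph")
    G = _to_networkx(graph)
    if kind == "betweenness":
        scores = nx.betweenness_centrality(G, normalized=False)
    elif kind == "closeness":
        scores = nx.closeness_centrality(G, wf_improved=False)
    else:
        raise ValueError(f"unknown path centrality {kind!r}")
    vals = np.array([scores[i] for i in range(graph.n_vertices)], dtype=float)
    return NodeScores(tuple(graph.nodes), vals, kind)


def local_clustering(graph: CoExpressionGraph) -> NodeScores:
    """Local clustering coefficient per node.

    Unweighted graphs use the triangle fraction; weighted graphs use
    Onnela's geometric-mean coefficient on weights normalized by the
    maximum weight.  Nodes of degree < 2 score 0.
    """
    G = _to_networkx(graph)
    weight = None if graph.is_unweighted else "weight"
    cc = nx.clustering(G, weight=weight)
    vals = np.array([cc[i] for i in range(graph.n_vertices)], dtype=float)
    return NodeScores(tuple(graph.nodes), vals, "clustering")


def average_shortest_path(graph: CoExpressionGraph) -> float:
    """Mean shortest-path length over reachable ordered pairs.

    Weighted edges have length 1/w (stronger association = shorter path);
    unreachable pairs are excluded, and a graph with no reachable pair
    scores 0.
    """
    A = graph.adjacency
    n = graph.n_vertices
    lengths = np.zeros_like(A)
    mask = A > 0
    lengths[mask] = 1.0 / A[mask]
    dist = shortest_path(csr_matrix(lengths), method="D", directed=False)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(dist) & off
    if not finite.any():
        return 0.0
    return float(dist[finite].mean())


def degree_distribution(
    graph: CoExpressionGraph,
    criterion: BandwidthCriterion = "sturges",
    grid: np.ndarray | None = None,
) -> SpectralDensity:
    """Gaussian KDE over node strengths (same machinery as spectral density)."""
    strengths = graph.adjacency.sum(axis=1)
    spec = Spectrum(np.sort(strengths)[::-1], 1)  # no rescaling for degrees
    return spectral_density(spec, criterion, grid)


# ---------------------------------------------------------------------------
# Graph distances
# ---------------------------------------------------------------------------

def adjacency_distance(
    a1: np.ndarray,
    a2: np.ndarray,
    kind: GraphDistanceKind,
    criterion: BandwidthCriterion = "sturges",
) -> float:
    """Distance Θ between two adjacency matrices over the same node order.

    Fast path used inside permutation loops; :func:`graph_distance` is the
    graph-object wrapper with node-set checking.
    """
    n = a1.shape[0]
    if kind == "spectral_js":
        e1 = np.linalg.eigvalsh(a1) / n
        e2 = np.linalg.eigvalsh(a2) / n
        d1, d2 = density_pair(e1, e2, criterion)
        return js_divergence(d1, d2)
    if kind == "degree_dist_js":
        s1 = a1.sum(axis=1)
        s2 = a2.sum(axis=1)
        d1, d2 = density_pair(s1, s2, criterion)
        return js_divergence(d1, d2)
    if kind == "degree_centrality_dist":
        return float(np.linalg.norm(a1.sum(axis=1) - a2.sum(axis=1)) / n)
    if kind == "eigenvector_centrality_dist":
        nodes = [str(i) for i in range(n)]
        v1 = eigenvector_centrality(CoExpressionGraph(nodes, a1)).values
        v2 = eigenvector_centrality(CoExpressionGraph(nodes, a2)).values
        return float(np.linalg.norm(v1 - v2) / n)
    if kind == "clustering_dist":
        nodes = [str(i) for i in range(n)]
        c1 = local_clustering(CoExpressionGraph(nodes, a1)).values
        c2 = local_clustering(CoExpressionGraph(nodes, a2)).values
        return float(np.linalg.norm(c1 - c2) / n)
    if kind == "shortest_path_absdiff":
        nodes = [str(i) for i in range(n)]
        p1 = average_shortest_path(CoExpressionGraph(nodes, a1))
        p2 = average_shortest_path(CoExpressionGraph(nodes, a2))
        return abs(p1 - p2)
    if kind == "entropy_absdiff":
        nodes = [str(i) for i in range(n)]
        h1 = spectral_entropy(spectral_density(
            adjacency_spectrum(CoExpressionGraph(nodes, a1)), criterion))
        h2 = spectral_entropy(spectral_density(
            adjacency_spectrum(CoExpressionGraph(nodes, a2)), criterion))
        return abs(h1 - h2)
    raise ValueError(f"unknown graph distance kind {kind!r}")


def graph_distance(
    g1: CoExpressionGraph,
    g2: CoExpressionGraph,
    kind: GraphDistanceKind,
    criterion: BandwidthCriterion = "sturges",
) -> float:
    """Distance Θ ≥ 0 between two graphs sharing node set and order."""
    if g1.nodes != g2.nodes:
        raise ValueError("graphs must share the same node set and order")
    return adjacency_distance(g1.adjacency, g2.adjacency, kind, criterion)


def set_properties(graph: CoExpressionGraph) -> GeneSetProperties:
    """Average structural properties of one phenotype's gene-set network."""
    deg = degree_centrality(graph).values
    if graph.adjacency.any():
        eig = float(eigenvector_centrality(graph).values.mean())
    else:
        eig = 0.0
    clus = float(local_clustering(graph).values.mean())
    if graph.n_vertices >= 2:
        ent = spectral_entropy(spectral_density(adjacency_spectrum(graph)))
    else:
        ent = float("nan")
    return GeneSetProperties(
        average_degree=float(deg.mean()),
        average_eigenvector=eig,
        average_clustering=clus,
        spectral_entropy=ent,
        average_shortest_path=average_shortest_path(graph),
    )
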