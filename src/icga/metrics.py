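"""Graph-metric battery on the connected constellation of each network.

Metrics are computed on the binarized post-threshold graph after removing
isolated nodes: edge count E, average degree k = 2E/n, triangle count,
average local clustering C, characteristic path length L (over reachable
pairs), and the small-worldness index

    sigma = (C / C_rand) / (L / L_rand)

with C_rand, L_rand averaged over Erdos-Renyi G(n, E) null graphs matched
on node and edge counts.  Triangle counts are normalized against the same
null.  Weights, when present, are ignored here: the battery describes the
thresholded topology.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np

from .io import to_networkx
from .types import MetricsRecord


def _as_nx(graph) -> nx.Graph:
    if isinstance(graph, nx.Graph):
        return graph
    return to_networkx(graph, weighted=False, binarize=True)


def connected_constellation(graph) -> nx.Graph:
    """Drop degree-0 nodes; the remaining 'constellation' carries the metrics."""
    g = _as_nx(graph)
    keep = [v for v, d in g.degree() if d > 0]
    return g.subgraph(keep).copy()


def characteristic_path_length(g: nx.Graph) -> tuple[float, float]:
    """Mean shortest-path length over reachable (connected) pairs.

    Returns ``(L, disconnected_fraction)`` where the fraction is the share
    of node pairs with no connecting path.  On a connected graph this is
    the ordinary characteristic path length with fraction 0.
    """
    n = g.number_of_nodes()
    if n < 2:
        return math.nan, 0.0
    total = 0.0
    reachable_pairs = 0
    for _, dists in nx.all_pairs_shortest_path_length(g):
        for d in dists.values():
            if d > 0:
                total += d
                reachable_pairs += 1
    all_pairs = n * (n - 1)
    if reachable_pairs == 0:
        return math.nan, 1.0
    return total / reachable_pairs, 1.0 - reachable_pairs / all_pairs


def triangle_count(g: nx.Graph) -> int:
    """Number of 3-cliques."""
    return sum(nx.triangles(g).values()) // 3


def basic_metrics(graph) -> tuple[int, float, int, float, float]:
    """(E, k, triangles, C, L) on the binarized constellation."""
    g = connected_constellation(graph)
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph: no connected nodes")
    e = g.number_of_edges()
    k = 2.0 * e / n
    tri = triangle_count(g)
    c = nx.average_clustering(g)
    ell, _ = characteristic_path_length(g)
    return e, k, tri, c, ell


def _null_graphs(n: int, e: int, n_random: int, seed):
    rng = np.random.default_rng(seed)
    for _ in range(n_random):
        yield nx.gnm_random_graph(n, e, seed=int(rng.integers(2**31)))


def small_worldness(graph, n_random: int = 20, seed=0) -> float:
    """Humphries–Gurney sigma against an Erdos-Renyi G(n, E) null.

    sigma > 1 marks a small-world topology: clustering well above the
    random expectation at near-random path lengths.  The null means are
    estimated over ``n_random`` seeded G(n, E) draws; L on any
    disconnected draw is taken over reachable pairs.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    g = connected_constellation(graph)
    n, e = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        raise ValueError("empty graph: no connected nodes")
    c = nx.average_clustering(g)
    ell, _ = characteristic_path_length(g)
    c_rand = []
    l_rand = []
    for h in _null_graphs(n, e, n_random, seed):
        c_rand.append(nx.average_clustering(h))
        l_r, _ = characteristic_path_length(h)
        l_rand.append(l_r)
    c_rand = float(np.mean(c_rand))
    l_rand = float(np.nanmean(l_rand))
    if c_rand == 0 or not np.isfinite(l_rand) or l_rand == 0 or not np.isfinite(ell):
        return math.nan
    return (c / c_rand) / (ell / l_rand)


def normalized_triangles(graph, n_random: int = 20, seed=0) -> float:
    """Triangle count over the mean triangle count of the G(n, E) null."""
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    g = connected_constellation(graph)
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph: no connected nodes")
    tri = triangle_count(g)
    null_tris = [
        triangle_count(h)
        for h in _null_graphs(g.number_of_nodes(), g.number_of_edges(), n_random, seed)
    ]
    mean_null = float(np.mean(null_tris))
    if mean_null == 0:
        return math.nan
    return tri / mean_null


def compute_metrics_record(
    graph, network_id=None, n_random: int = 20, seed=0
) -> MetricsRecord:
    """Assemble the full battery for one graph.

    An edgeless graph yields a record with zero nodes and NaN-flagged
    metrics rather than an error, so cohort tables stay rectangular.
    """
    g = _as_nx(graph)
    constellation = connected_constellation(g)
    if network_id is None:
        network_id = getattr(graph, "component_id", None)
    if constellation.number_of_nodes() == 0:
        return MetricsRecord(
            network_id=network_id,
            n_connected_nodes=0,
            n_edges=0,
            avg_degree=0.0,
            n_triangles=0,
            triangles_normalized=math.nan,
            clustering=math.nan,
            path_length=math.nan,
            small_worldness=math.nan,
        )
    e, k, tri, c, ell = basic_metrics(constellation)
    _, disc = characteristic_path_length(constellation)
    return MetricsRecord(
        network_id=network_id,
        n_connected_nodes=constellation.number_of_nodes(),
        n_edges=e,
        avg_degree=k,
        n_triangles=tri,
        triangles_normalized=normalized_triangles(constellation, n_random, seed),
        clustering=c,
        path_length=ell,
        small_worldness=small_worldness(constellation, n_random, seed),
        disconnected_pair_fraction=disc,
    )
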