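"""Binary graph statistics.

Six local metrics (degree, clustering, betweenness-centrality, mean incident
edge length, local efficiency, eigenvector centrality) and four global ones
(modularity Q, degree assortativity, global clustering, global efficiency).
Shortest-path work runs through python-igraph's C core so that the many
thousands of simulated networks scored during a grid search stay cheap.

Conventions (fixed and relied on by the evaluation stage):

* betweenness is the raw shortest-path count (unnormalised); fingerprints use
  correlations, which are invariant to any affine normalisation.
* clustering of a node with degree < 2 is 0; local efficiency and mean edge
  length of an isolated node are 0.
* eigenvector centrality is the unit-norm principal eigenvector of the
  adjacency matrix (entrywise absolute value), computed by dense symmetric
  eigendecomposition — deterministic, and defined for disconnected graphs.
* disconnected pairs contribute efficiency 0 (the 1/inf convention).
* global clustering is nodal clustering averaged over nodes.
* modularity Q is evaluated on a Louvain partition with a fixed seed.
"""

from __future__ import annotations

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .graphs import SpatialGraph

__all__ = [
    "NODAL_METRICS",
    "nodal_metrics",
    "global_metrics",
    "coefficient_of_variation",
]

NODAL_METRICS = (
    "degree",
    "clustering",
    "betweenness",
    "edge_length",
    "local_efficiency",
    "eigenvector_centrality",
)


def _to_igraph(graph: SpatialGraph) -> ig.Graph:
    edges = graph.edge_list()
    return ig.Graph(n=graph.n_nodes, edges=[tuple(e) for e in edges])


def _mean_inverse_distance(g: ig.Graph) -> float:
    """Mean of 1/d over ordered node pairs; disconnected pairs count 0."""
    n = g.vcount()
    if n < 2:
        return 0.0
    d = np.asarray(g.distances())
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def _local_efficiency(graph: SpatialGraph, g: ig.Graph) -> np.ndarray:
    adj = graph.adjacency
    eff = np.zeros(graph.n_nodes)
    for v in range(graph.n_nodes):
        nbrs = np.flatnonzero(adj[v])
        if nbrs.size < 2:
            continue
        eff[v] = _mean_inverse_distance(g.induced_subgraph(list(nbrs)))
    return eff


def _mean_incident_length(graph: SpatialGraph) -> np.ndarray:
    D = graph.distance_matrix()
    masked = D * graph.adjacency
    deg = graph.degrees()
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(deg > 0, masked.sum(axis=1) / deg, 0.0)
    return out


def _eigenvector_centrality(graph: SpatialGraph) -> np.ndarray:
    if graph.n_edges == 0:
        v = np.ones(graph.n_nodes)
        return v / np.linalg.norm(v)
    vals, vecs = np.linalg.eigh(graph.adjacency.astype(float))
    v = np.abs(vecs[:, np.argmax(vals)])
    return v / np.linalg.norm(v)


def nodal_metrics(graph: SpatialGraph) -> pd.DataFrame:
    """Table of the six local metrics, one row per node."""
    g = _to_igraph(graph)
    clustering = np.asarray(
        g.transitivity_local_undirected(mode="zero"), dtype=float
    )
    betweenness = np.asarray(g.betweenness(), dtype=float)
    return pd.DataFrame(
        {
            "degree": graph.degrees().astype(float),
            "clustering": clustering,
            "betweenness": betweenness,
            "edge_length": _mean_incident_length(graph),
            "local_efficiency": _local_efficiency(graph, g),
            "eigenvector_centrality": _eigenvector_centrality(graph),
        }
    )


def global_metrics(graph: SpatialGraph, partition_seed: int = 0) -> dict[str, float]:
    """Modularity Q, assortativity, global clustering, global efficiency."""
    g = _to_igraph(graph)
    nxg = nx.from_numpy_array(np.asarray(graph.adjacency))
    if graph.n_edges > 0:
        communities = nx.community.louvain_communities(nxg, seed=partition_seed)
        modularity = nx.community.modularity(nxg, communities)
        try:
            assortativity = nx.degree_assortativity_coefficient(nxg)
        except (ZeroDivisionError, ValueError):
            assortativity = float("nan")
    else:
        modularity = float("nan")
        assortativity = float("nan")
    clustering = np.asarray(
        g.transitivity_local_undirected(mode="zero"), dtype=float
    )
    return {
        "modularity": float(modularity),
        "assortativity": float(assortativity),
        "global_clustering": float(clustering.mean()) if len(clustering) else 0.0,
        "global_efficiency": _mean_inverse_distance(g),
    }


def global_efficiency(graph: SpatialGraph) -> float:
    """Mean inverse shortest-path length over all node pairs."""
    return _mean_inverse_distance(_to_igraph(graph))


def coefficient_of_variation(metric_matrix: np.ndarray) -> np.ndarray:
    """Per-node CV = sample SD / mean across participants (rows).

    Nodes with zero mean get NaN (undefined), never +/-inf.
    """
    m = np.asarray(metric_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2:
        raise InvalidInputError("need a (participants >= 2) x nodes matrix")
    mean = m.mean(axis=0)
    sd = m.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean != 0, sd / mean, np.nan)
    return cv
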