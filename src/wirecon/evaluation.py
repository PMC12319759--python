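"""Model-fit criteria and model selection.

Three complementary criteria compare a simulated network with its empirical
target:

* **energy** E = max(KS_k, KS_c, KS_b, KS_e) — the largest of four two-sample
  Kolmogorov–Smirnov statistics over the nodal degree, clustering and
  betweenness distributions and the distribution of existing edge lengths.
  A global, distribution-level measure: permuting node labels leaves it
  unchanged.
* **topological fingerprint dissimilarity** — the Frobenius norm of the
  difference between two 6x6 correlation matrices of local nodal metrics.
* **spatial similarity** — the node-matched Pearson correlation of degree,
  sensitive to where in space the edges land.

Grid search minimises energy over an (eta, gamma) lattice; rules are compared
by cumulative rank over the three criteria.  A Maslov–Sneppen rewiring null
(degree-preserving random edge swaps) supports topology-randomised baselines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .gnm import GNMParams, derive_seed, simulate
from .graphs import SpatialGraph
from .metrics import NODAL_METRICS, nodal_metrics

__all__ = [
    "EnergyResult",
    "ks_statistic",
    "energy",
    "fingerprint",
    "tf_dissimilarity",
    "spatial_similarity",
    "GridSearchResult",
    "grid_search",
    "rank_models",
    "maslov_sneppen",
]


@dataclass(frozen=True)
class EnergyResult:
    ks_degree: float
    ks_clustering: float
    ks_betweenness: float
    ks_edge_length: float

    @property
    def energy(self) -> float:
        return max(
            self.ks_degree,
            self.ks_clustering,
            self.ks_betweenness,
            self.ks_edge_length,
        )

    def components(self) -> tuple[float, float, float, float]:
        return (
            self.ks_degree,
            self.ks_clustering,
            self.ks_betweenness,
            self.ks_edge_length,
        )


def ks_statistic(sample_a, sample_b) -> float:
    """Two-sample KS statistic (sup of empirical CDF difference)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidInputError("KS statistic requires non-empty samples")
    return _ks2(a, b)


def _ks2(a: np.ndarray, b: np.ndarray) -> float:
    """Sup |ECDF_a - ECDF_b| via a merged sorted grid (no p-value)."""
    a = np.sort(a)
    b = np.sort(b)
    grid = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, grid, side="right") / a.size
    cdf_b = np.searchsorted(b, grid, side="right") / b.size
    return float(np.abs(cdf_a - cdf_b).max())


def _energy_inputs(graph: SpatialGraph) -> dict[str, np.ndarray]:
    # only the four energy distributions; skips the costlier fingerprint
    # metrics (local efficiency, eigenvector centrality).  Values are snapped
    # to 9 decimals so that graphs identical up to node relabelling (whose
    # shortest-path sums can differ in the last ulp) compare as equal under
    # the discontinuous KS statistic.
    import igraph as ig

    adj = graph.adjacency.astype(float)
    deg = adj.sum(axis=0)
    triangles = ((adj @ adj) * adj).sum(axis=1) / 2.0
    denom = deg * (deg - 1) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        clustering = np.where(denom > 0, triangles / denom, 0.0)
    g = ig.Graph(n=graph.n_nodes, edges=[tuple(e) for e in graph.edge_list()])
    return {
        "degree": deg,
        "clustering": clustering.round(9),
        "betweenness": np.asarray(g.betweenness(), dtype=float).round(9),
        "edge_length": graph.edge_lengths().round(9),
    }


def energy(
    simulated: SpatialGraph,
    empirical: SpatialGraph,
    empirical_inputs: dict[str, np.ndarray] | None = None,
) -> EnergyResult:
    """Energy of ``simulated`` against ``empirical``.

    ``empirical_inputs`` may carry precomputed target distributions (from a
    previous call) to avoid rescoring the target in a grid search.
    """
    if simulated.n_edges == 0 or empirical.n_edges == 0:
        raise InvalidInputError("energy undefined for edgeless graphs")
    if simulated.n_nodes != empirical.n_nodes:
        raise InvalidInputError("graphs must share a node set")
    sim = _energy_inputs(simulated)
    emp = empirical_inputs or _energy_inputs(empirical)
    return EnergyResult(
        ks_degree=ks_statistic(sim["degree"], emp["degree"]),
        ks_clustering=ks_statistic(sim["clustering"], emp["clustering"]),
        ks_betweenness=ks_statistic(sim["betweenness"], emp["betweenness"]),
        ks_edge_length=ks_statistic(sim["edge_length"], emp["edge_length"]),
    )


def fingerprint(graph: SpatialGraph) -> np.ndarray:
    """6x6 Pearson correlation matrix of the six local nodal metrics.

    Zero-variance metrics (e.g. degree on a regular lattice) get their row and
    column set to 0 (diagonal stays 1) so fingerprints remain comparable.
    """
    if graph.n_nodes < 3:
        raise InvalidInputError("fingerprint requires >= 3 nodes")
    table = nodal_metrics(graph)[list(NODAL_METRICS)].to_numpy()
    sd = table.std(axis=0)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            "zero-variance nodal metric(s) in fingerprint: "
            + ", ".join(np.array(NODAL_METRICS)[flat]),
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(table, rowvar=False)
    corr[flat, :] = 0.0
    corr[:, flat] = 0.0
    np.fill_diagonal(corr, 1.0)
    return corr


def tf_dissimilarity(a: np.ndarray, b: np.ndarray) -> float:
    """Frobenius norm of the difference between two fingerprints."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise InvalidInputError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b, ord="fro"))


def spatial_similarity(simulated: SpatialGraph, empirical: SpatialGraph) -> float:
    """Node-matched Pearson correlation of degree (NaN if degenerate)."""
    if simulated.n_nodes != empirical.n_nodes:
        raise InvalidInputError("graphs must share a node set")
    a = simulated.degrees().astype(float)
    b = empirical.degrees().astype(float)
    if a.std() == 0 or b.std() == 0:
        warnings.warn("zero degree variance: spatial similarity undefined",
                      stacklevel=2)
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


@dataclass(frozen=True)
class GridSearchResult:
    """Energy landscape of one rule over an (eta, gamma) lattice."""

    records: pd.DataFrame  # eta, gamma, repeat, ks_*, energy
    best_params: GNMParams
    best_energy: float
    top_fraction_window: dict[str, tuple[float, float]]
    rule: str


def grid_search(
    seed: SpatialGraph,
    target: SpatialGraph,
    rule: str,
    grid: np.ndarray,
    rng_seed: int,
    repeats: int = 1,
    top_fraction: float = 0.10,
    epsilon: float = 1e-6,
) -> GridSearchResult:
    """One simulation + energy per grid point (times ``repeats``).

    The per-point RNG stream is derived from ``rng_seed`` and the parameter
    values themselves, so duplicated grid points replay identically.  Best
    point = argmin energy, ties broken by smaller KS sum then lexicographic
    (eta, gamma).  The top-fraction window reports the [min, max] of eta and
    gamma over the lowest-energy fraction of records.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise InvalidInputError("grid must be non-empty")
    emp_inputs = _energy_inputs(target)
    rows = []
    for eta, gamma in grid:
        params = GNMParams(eta=eta, gamma=gamma, epsilon=epsilon)
        for rep in range(repeats):
            sub = derive_seed(rng_seed, rule, float(eta), float(gamma), rep)
            trace = simulate(seed, target.n_edges, rule, params, sub)
            res = energy(trace.final, target, empirical_inputs=emp_inputs)
            rows.append(
                (eta, gamma, rep, *res.components(), res.energy)
            )
    records = pd.DataFrame(
        rows,
        columns=[
            "eta", "gamma", "repeat",
            "ks_degree", "ks_clustering", "ks_betweenness", "ks_edge_length",
            "energy",
        ],
    )
    records["ks_sum"] = records[
        ["ks_degree", "ks_clustering", "ks_betweenness", "ks_edge_length"]
    ].sum(axis=1)
    # with repeats, points are judged on their mean energy across repeats
    per_point = (
        records.groupby(["eta", "gamma"], as_index=False)[["energy", "ks_sum"]]
        .mean()
    )
    order = per_point.sort_values(
        ["energy", "ks_sum", "eta", "gamma"], kind="mergesort"
    )
    best = order.iloc[0]
    n_top = max(1, int(np.ceil(top_fraction * len(order))))
    top = order.iloc[:n_top]
    window = {
        "eta": (float(top["eta"].min()), float(top["eta"].max())),
        "gamma": (float(top["gamma"].min()), float(top["gamma"].max())),
    }
    return GridSearchResult(
        records=records.drop(columns="ks_sum"),
        best_params=GNMParams(float(best["eta"]), float(best["gamma"]),
                              epsilon=epsilon),
        best_energy=float(best["energy"]),
        top_fraction_window=window,
        rule=rule,
    )


def rank_models(criteria: pd.DataFrame) -> pd.DataFrame:
    """Cumulative-rank model selection over the five wiring rules.

    ``criteria`` is indexed by rule with columns ``energy`` (lower better),
    ``tf_dissimilarity`` (lower better) and ``spatial_r`` (higher better).
    Returns the table sorted by rank sum (winner first); ties broken by the
    energy rank.
    """
    required = {"energy", "tf_dissimilarity", "spatial_r"}
    missing = required - set(criteria.columns)
    if missing or criteria[list(required)].isna().any().any():
        raise InvalidInputError(f"missing criteria: {sorted(missing) or 'NaNs'}")
    out = criteria.copy()
    out["rank_energy"] = out["energy"].rank(method="min")
    out["rank_tf"] = out["tf_dissimilarity"].rank(method="min")
    out["rank_spatial"] = out["spatial_r"].rank(method="min", ascending=False)
    out["rank_sum"] = out[["rank_energy", "rank_tf", "rank_spatial"]].sum(axis=1)
    return out.sort_values(["rank_sum", "rank_energy"], kind="mergesort")


def maslov_sneppen(graph: SpatialGraph, rng_seed: int) -> SpatialGraph:
    """Degree-preserving rewiring: one accepted double-edge swap per edge.

    Swaps (a-b, c-d) -> (a-d, c-b) are drawn uniformly at random and rejected
    if they would create a self-loop or multi-edge, until |E| swaps have been
    accepted (or an attempt budget is exhausted).  Graphs too small or dense
    to swap are returned unchanged with a warning.
    """
    m = graph.n_edges
    if m < 2:
        warnings.warn("graph too small to rewire; returning input", stacklevel=2)
        return graph
    rng = np.random.default_rng(rng_seed)
    adj = graph.adjacency.copy()
    edges = graph.edge_list()
    accepted = 0
    attempts = 0
    max_attempts = 100 * m
    while accepted < m and attempts < max_attempts:
        attempts += 1
        e1, e2 = rng.integers(0, m, size=2)
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if rng.random() < 0.5:
            c, d = d, c
        # propose a-d and c-b
        if len({a, b, c, d}) < 4:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = adj[b, a] = 0
        adj[c, d] = adj[d, c] = 0
        adj[a, d] = adj[d, a] = 1
        adj[c, b] = adj[b, c] = 1
        edges[e1] = sorted((a, d))
        edges[e2] = sorted((c, b))
        accepted += 1
    if accepted == 0:
        warnings.warn("no feasible swaps found; returning input", stacklevel=2)
        return graph
    return graph.with_adjacency(adj)
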