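"""The generative network model engine.

A generative network model (GNM) grows a binary network from a sparse seed by
adding one edge per iteration.  The probability that the unconnected pair
(i, j) receives the next edge is

    P_ij  ∝  D_ij ** eta  *  (K_ij + epsilon) ** gamma

where D is the fixed Euclidean distance matrix (the wiring *cost*), K is a
topological *value* matrix recomputed after every addition, eta < 0 penalises
long connections, and gamma weights topological value.  epsilon is a small
positive constant keeping the probability defined when K_ij = 0.

Five value rules are supported: ``spatial`` (K ≡ 1, pure distance penalty),
``neighbours`` (shared-neighbour count), ``matching`` (normalised
neighbourhood overlap), ``clustering_average`` and ``degree_average`` (mean of
the two nodal statistics).  Both the power-law form and the rule set follow
the standard binary connectome GNM formulation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .errors import (
    InfeasibleTargetError,
    InvalidRuleError,
    InvalidSpecError,
    MissingTraceError,
    SaturatedGraphError,
)
from .graphs import SpatialGraph

__all__ = [
    "GNMParams",
    "WIRING_RULES",
    "SimulationTrace",
    "topological_value",
    "wiring_probabilities",
    "simulate",
    "parameterised_nodal_terms",
    "build_grid",
    "derive_seed",
]

WIRING_RULES = (
    "spatial",
    "matching",
    "neighbours",
    "clustering_average",
    "degree_average",
)


@dataclass(frozen=True)
class GNMParams:
    """Wiring-equation exponents.

    eta: exponent on the distance term D (negative = distance penalty).
    gamma: exponent on the topological value term K.
    epsilon: small additive constant on K so probabilities stay defined.
    """

    eta: float
    gamma: float
    epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if not np.isfinite(self.eta) or not np.isfinite(self.gamma):
            raise InvalidSpecError("eta and gamma must be finite")
        if self.epsilon <= 0:
            raise InvalidSpecError("epsilon must be > 0")


@dataclass(frozen=True)
class SimulationTrace:
    """Record of one simulation run.

    ``nodal_cost[i]`` is the mean over iterations of sum_j D_ij**eta (constant
    across iterations since D is fixed); ``nodal_value[i]`` the mean over
    iterations of sum_j (K_ij + eps)**gamma.  ``mean_pair_probability`` is the
    iteration-averaged wiring probability of every (i < j) pair (0 for pairs
    never on the candidate list, e.g. seed edges).  ``probability_records``
    optionally holds the full per-iteration candidate probability matrix
    (iterations x pairs) — memory-guarded, for small graphs only.
    """

    seed: SpatialGraph
    final: SpatialGraph
    added_edges: tuple[tuple[int, int], ...]
    params: GNMParams
    rule: str
    rng_seed: int
    nodal_cost: np.ndarray | None = None
    nodal_value: np.ndarray | None = None
    mean_pair_probability: np.ndarray | None = None
    probability_records: np.ndarray | None = None


def _validate_rule(rule: str) -> None:
    if rule not in WIRING_RULES:
        raise InvalidRuleError(
            f"unknown rule {rule!r}; expected one of {WIRING_RULES}"
        )


def _value_matrix(adj: np.ndarray, rule: str) -> np.ndarray:
    """K for a float {0,1} adjacency. Symmetric, non-negative, zero diagonal."""
    n = adj.shape[0]
    if rule == "spatial":
        K = np.ones((n, n))
    elif rule == "neighbours":
        K = adj @ adj
    elif rule == "matching":
        inter = adj @ adj
        deg = adj.sum(axis=0)
        # neighbourhood sizes excluding the pair itself
        denom = deg[:, None] + deg[None, :] - 2.0 * adj
        with np.errstate(invalid="ignore", divide="ignore"):
            K = np.where(denom > 0, 2.0 * inter / denom, 0.0)
    elif rule == "clustering_average":
        deg = adj.sum(axis=0)
        triangles = ((adj @ adj) * adj).sum(axis=1) / 2.0
        denom = deg * (deg - 1) / 2.0
        with np.errstate(invalid="ignore", divide="ignore"):
            clust = np.where(denom > 0, triangles / denom, 0.0)
        K = (clust[:, None] + clust[None, :]) / 2.0
    elif rule == "degree_average":
        deg = adj.sum(axis=0)
        K = (deg[:, None] + deg[None, :]) / 2.0
    else:  # pragma: no cover - guarded by _validate_rule
        raise InvalidRuleError(rule)
    np.fill_diagonal(K, 0.0)
    return K


def topological_value(graph: SpatialGraph, rule: str) -> np.ndarray:
    """Topological value matrix K for ``graph`` under ``rule``.

    ``matching`` uses the Dice-normalised overlap of the two neighbourhoods
    excluding the pair itself (1 for identical non-empty neighbourhoods, 0
    when both are empty); ``neighbours`` is the raw shared-neighbour count.
    """
    _validate_rule(rule)
    return _value_matrix(graph.adjacency.astype(float), rule)


def wiring_probabilities(
    K: np.ndarray,
    D: np.ndarray,
    current: SpatialGraph,
    params: GNMParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Probability vector over unconnected (i < j) pairs.

    Returns ``(pairs, probabilities)`` where ``pairs`` is an (m, 2) array of
    candidate pairs in lexicographic order and ``probabilities`` sums to 1.
    """
    n = current.n_nodes
    iu, ju = np.triu_indices(n, 1)
    if np.any(D[iu, ju] <= 0):
        raise InvalidSpecError("distances must be strictly positive off-diagonal")
    free = current.adjacency[iu, ju] == 0
    if not free.any():
        raise SaturatedGraphError("no unconnected pairs remain")
    i, j = iu[free], ju[free]
    w = D[i, j] ** params.eta * (K[i, j] + params.epsilon) ** params.gamma
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        raise InvalidSpecError("wiring weights are degenerate (overflow or all-zero)")
    return np.column_stack([i, j]), w / total


def simulate(
    seed: SpatialGraph,
    target_edges: int,
    rule: str,
    params: GNMParams,
    rng_seed: int,
    record: bool | str = False,
    record_probabilities: bool = False,
) -> SimulationTrace:
    """Grow the network from ``seed`` to ``target_edges`` edges.

    One edge is added per iteration, sampled by inverse-CDF over the
    lexicographically ordered candidate list (bit-reproducible for a fixed
    ``rng_seed``).  K is recomputed after every addition.  With
    ``record=True`` the trace carries the parameterised nodal terms and the
    iteration-averaged pair probabilities; ``record="pairs"`` records only
    the latter (cheaper); ``record_probabilities=True`` additionally stores
    the full per-iteration probability matrix (use only on small graphs).
    """
    _validate_rule(rule)
    n = seed.n_nodes
    max_edges = n * (n - 1) // 2
    if target_edges < seed.n_edges or target_edges > max_edges:
        raise InfeasibleTargetError(
            f"target_edges={target_edges} infeasible from seed with "
            f"{seed.n_edges} edges on {n} nodes (max {max_edges})"
        )
    rng = np.random.default_rng(rng_seed)
    D = seed.distance_matrix()
    iu, ju = np.triu_indices(n, 1)
    if np.any(D[iu, ju] <= 0):
        raise InvalidSpecError("coincident node coordinates: zero distance")

    adj = seed.adjacency.astype(float).copy()
    free = adj[iu, ju] == 0
    Dpow = D[iu, ju] ** params.eta
    n_add = target_edges - seed.n_edges
    added: list[tuple[int, int]] = []

    record_nodal = record is True
    nodal_cost = nodal_value = pair_acc = prob_records = None
    if record:
        pair_acc = np.zeros(iu.size)
        if record_probabilities:
            prob_records = np.zeros((n_add, iu.size))
    if record_nodal:
        with np.errstate(divide="ignore"):
            Dfull = D ** params.eta
        np.fill_diagonal(Dfull, 0.0)
        nodal_cost = Dfull.sum(axis=1)  # constant across iterations
        nodal_value = np.zeros(n)

    for step in range(n_add):
        K = _value_matrix(adj, rule)
        w = Dpow * (K[iu, ju] + params.epsilon) ** params.gamma
        w[~free] = 0.0
        total = w.sum()
        if not np.isfinite(total) or total <= 0:
            raise InvalidSpecError("degenerate wiring weights during simulation")
        p = w / total
        if record:
            pair_acc += p
            if record_probabilities:
                prob_records[step] = p
        if record_nodal:
            Kp = (K + params.epsilon) ** params.gamma
            np.fill_diagonal(Kp, 0.0)
            nodal_value += Kp.sum(axis=1)
        cum = np.cumsum(p)
        idx = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
        idx = min(idx, len(p) - 1)
        i, j = int(iu[idx]), int(ju[idx])
        adj[i, j] = adj[j, i] = 1.0
        free[idx] = False
        added.append((i, j))

    if record and n_add > 0:
        pair_acc = pair_acc / n_add
    if record_nodal and n_add > 0:
        nodal_value = nodal_value / n_add
    elif record_nodal:
        # zero-addition trace: report the seed's own terms
        K = _value_matrix(adj, rule)
        Kp = (K + params.epsilon) ** params.gamma
        np.fill_diagonal(Kp, 0.0)
        nodal_value = Kp.sum(axis=1)

    final = seed.with_adjacency(adj.astype(np.int8))
    return SimulationTrace(
        seed=seed,
        final=final,
        added_edges=tuple(added),
        params=params,
        rule=rule,
        rng_seed=int(rng_seed),
        nodal_cost=nodal_cost,
        nodal_value=nodal_value,
        mean_pair_probability=pair_acc,
        probability_records=prob_records,
    )


def parameterised_nodal_terms(
    trace: SimulationTrace,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-node parameterised wiring cost and value from a recorded trace.

    cost_i = mean over iterations of sum_j D_ij**eta (D fixed, so constant);
    value_i = mean over iterations of sum_j (K_ij + eps)**gamma.
    """
    if trace.nodal_cost is None or trace.nodal_value is None:
        raise MissingTraceError("simulation was not run with record=True")
    return trace.nodal_cost.copy(), trace.nodal_value.copy()


def build_grid(
    budget: int,
    eta_range: tuple[float, float] = (-7.0, 7.0),
    gamma_range: tuple[float, float] = (-7.0, 7.0),
) -> np.ndarray:
    """Equally spaced (eta, gamma) grid with at most ``budget`` points.

    Uses m = floor(sqrt(budget)) points per axis including both endpoints,
    returning the m**2 unique Cartesian pairs (e.g. a 100,000 budget yields
    316**2 = 99,856 pairs).
    """
    if budget < 1:
        raise InvalidSpecError("budget must be >= 1")
    if eta_range[0] >= eta_range[1] or gamma_range[0] >= gamma_range[1]:
        raise InvalidSpecError("parameter ranges must be non-degenerate")
    m = int(np.floor(np.sqrt(budget)))
    etas = np.linspace(eta_range[0], eta_range[1], m)
    gammas = np.linspace(gamma_range[0], gamma_range[1], m)
    ee, gg = np.meshgrid(etas, gammas, indexing="ij")
    return np.column_stack([ee.ravel(), gg.ravel()])


def write_trace_jsonl(trace: SimulationTrace, path) -> None:
    """Serialise a trace as JSON lines.

    Line 1 is a header record (rule, eta, gamma, epsilon, rng_seed, node and
    edge counts); each following line is one iteration:
    ``{"step": t, "edge": [i, j]}`` plus, when the trace was recorded with
    full probabilities, ``"max_probability"`` of that iteration's candidate
    distribution.
    """
    import json

    with open(path, "w") as fh:
        header = {
            "rule": trace.rule,
            "eta": trace.params.eta,
            "gamma": trace.params.gamma,
            "epsilon": trace.params.epsilon,
            "rng_seed": trace.rng_seed,
            "n_nodes": trace.seed.n_nodes,
            "seed_edges": trace.seed.n_edges,
            "final_edges": trace.final.n_edges,
        }
        fh.write(json.dumps(header) + "\n")
        for step, (i, j) in enumerate(trace.added_edges):
            rec: dict = {"step": step, "edge": [int(i), int(j)]}
            if trace.probability_records is not None:
                rec["max_probability"] = float(
                    trace.probability_records[step].max()
                )
            fh.write(json.dumps(rec) + "\n")


def derive_seed(base_seed: int, *parts: float | int | str) -> int:
    """Stable sub-seed (< 2**31) from a base seed and arbitrary labels.

    Identical inputs give identical streams on every platform, so duplicate
    grid points replay the same simulation.
    """
    payload = repr((int(base_seed),) + tuple(parts)).encode()
    return zlib.crc32(payload) & 0x7FFFFFFF
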