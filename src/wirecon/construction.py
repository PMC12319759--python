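"""Thresholding procedures turning weighted connectome stacks into binary
modelling targets and a common simulation seed.

The pipeline mirrors standard group-connectome practice: (1) a prevalence
mask removes edges seen in too few participants; (2) a distance-dependent
consensus builds a single group target whose edge-length distribution tracks
the typical participant rather than over-representing short edges; (3) a raw
streamline-count threshold binarises each participant's own target; (4) a
high-prevalence (95%) mask over the binary targets yields the sparse seed
network shared by every simulation.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np

from .errors import InvalidInputError
from .graphs import SpatialGraph, WeightedStack

__all__ = [
    "prevalence_threshold",
    "distance_dependent_consensus",
    "streamline_threshold",
    "seed_network",
]

log = logging.getLogger(__name__)


def prevalence_threshold(stack: WeightedStack, prevalence: float) -> WeightedStack:
    """Keep edges whose nonzero count across participants meets the cut.

    An edge survives (in every participant, weights preserved) iff it is
    nonzero in at least ceil(prevalence * participants) participants.
    """
    if not 0 < prevalence <= 1:
        raise InvalidInputError("prevalence must be in (0, 1]")
    counts = (stack.weights > 0).sum(axis=0)
    need = math.ceil(prevalence * stack.n_participants)
    mask = counts >= need
    return WeightedStack(stack.weights * mask[None, :, :])


def streamline_threshold(weights: np.ndarray, threshold: float,
                         coordinates: np.ndarray | None = None) -> SpatialGraph:
    """Binary graph of edges with weight >= threshold (and weight > 0)."""
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise InvalidInputError("weights must be non-negative")
    if threshold < 0:
        raise InvalidInputError("threshold must be >= 0")
    adj = ((w >= threshold) & (w > 0)).astype(np.int8)
    adj = np.triu(adj, 1)
    adj = adj + adj.T
    if coordinates is None:
        coordinates = np.zeros((w.shape[0], 3))
    return SpatialGraph(adj, coordinates)


def _consensus_from_order(counts: np.ndarray, order: np.ndarray,
                          n_keep: int, n: int) -> np.ndarray:
    adj = np.zeros((n, n), dtype=np.int8)
    iu, ju = np.triu_indices(n, 1)
    keep = order[:n_keep]
    adj[iu[keep], ju[keep]] = 1
    return adj + adj.T


def distance_dependent_consensus(
    stack: WeightedStack,
    distances: np.ndarray,
    n_bins: int = 10,
    coordinates: np.ndarray | None = None,
) -> SpatialGraph:
    """Group consensus network with a distance-dependent edge quota.

    Candidate edges (nonzero in >= 1 participant) are split into ``n_bins``
    equal-frequency length bins; each bin keeps its most prevalent edges, with
    a quota proportional to how many participant edges fall in that bin, so
    that the consensus edge count matches the mean participant edge count and
    the group edge-length distribution tracks the typical participant.  Ties
    in prevalence break by higher mean weight, then lexicographic pair index.
    """
    if n_bins < 1:
        raise InvalidInputError("n_bins must be >= 1")
    n = stack.n_nodes
    iu, ju = np.triu_indices(n, 1)
    w = stack.weights[:, iu, ju]  # participants x pairs
    present = w > 0
    counts = present.sum(axis=0)
    candidates = np.flatnonzero(counts > 0)
    if candidates.size == 0:
        raise InvalidInputError("stack has no edges")
    target = int(round(present.sum(axis=1).mean()))
    mean_w = w.mean(axis=0)
    d = np.asarray(distances)[iu, ju]

    # equal-frequency length bins over candidate edges
    order_by_len = candidates[np.argsort(d[candidates], kind="mergesort")]
    bins = np.array_split(order_by_len, n_bins)
    # participant edge mass per bin sets the quota
    masses = np.array([present[:, b].sum() for b in bins], dtype=float)
    total_mass = masses.sum()
    kept: list[np.ndarray] = []
    for b, mass in zip(bins, masses):
        if b.size == 0:
            log.warning("empty length bin skipped in consensus thresholding")
            continue
        quota = int(round(target * mass / total_mass))
        quota = min(quota, b.size)
        if quota == 0:
            continue
        # most prevalent first; ties by mean weight then pair index
        key = np.lexsort((b, -mean_w[b], -counts[b]))
        kept.append(b[key][:quota])
    keep = np.concatenate(kept) if kept else np.empty(0, dtype=int)
    adj = np.zeros((n, n), dtype=np.int8)
    adj[iu[keep], ju[keep]] = 1
    adj = adj + adj.T
    if coordinates is None:
        coordinates = np.zeros((n, 3))
    return SpatialGraph(adj, coordinates)


def seed_network(
    graphs: list[SpatialGraph], prevalence: float = 0.95
) -> SpatialGraph:
    """Edges present in at least ``prevalence`` of the binary participant graphs.

    May legitimately be empty (simulations then start from an empty seed); a
    warning is logged in that case.  Density is reported in the run log.
    """
    if not graphs:
        raise InvalidInputError("need at least one graph")
    n = graphs[0].n_nodes
    if any(g.n_nodes != n for g in graphs):
        raise InvalidInputError("all graphs must share a node set")
    if not 0 < prevalence <= 1:
        raise InvalidInputError("prevalence must be in (0, 1]")
    counts = np.sum([g.adjacency for g in graphs], axis=0)
    need = math.ceil(prevalence * len(graphs))
    adj = (counts >= need).astype(np.int8)
    seed = SpatialGraph(adj, graphs[0].coordinates, graphs[0].labels)
    if seed.n_edges == 0:
        warnings.warn("seed network is empty; simulations start from scratch",
                      stacklevel=2)
    log.info("seed network density: %.4f", seed.density)
    return seed
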