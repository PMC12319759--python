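"""Core containers: binary spatially embedded graphs and weighted stacks.

A :class:`SpatialGraph` couples a binary, undirected, zero-diagonal adjacency
matrix with 3-D node coordinates in millimetres.  It is the unit of currency
for every stage of the pipeline: thresholded connectomes, simulation seeds and
targets, and simulated networks all use it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .errors import InvalidInputError

__all__ = ["SpatialGraph", "WeightedStack", "euclidean_distances"]


def euclidean_distances(coordinates: np.ndarray) -> np.ndarray:
    """Dense symmetric Euclidean distance matrix from an (n, 3) table."""
    coordinates = np.asarray(coordinates, dtype=float)
    if coordinates.ndim != 2 or coordinates.shape[1] != 3:
        raise InvalidInputError(
            f"coordinates must be (n, 3); got {coordinates.shape}"
        )
    return squareform(pdist(coordinates))


@dataclass(frozen=True)
class SpatialGraph:
    """Binary undirected graph embedded in Euclidean space.

    Parameters
    ----------
    adjacency
        (n, n) symmetric binary matrix with zero diagonal.
    coordinates
        (n, 3) node coordinates in mm.
    labels
        Optional node names, length n.
    """

    adjacency: np.ndarray
    coordinates: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise InvalidInputError("adjacency must be square")
        if not np.array_equal(adj, adj.T):
            raise InvalidInputError("adjacency must be symmetric")
        if np.any(np.diag(adj) != 0):
            raise InvalidInputError("adjacency must have a zero diagonal")
        if not np.isin(adj, (0, 1)).all():
            raise InvalidInputError("adjacency entries must be 0 or 1")
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.shape != (adj.shape[0], 3):
            raise InvalidInputError(
                f"coordinates must be ({adj.shape[0]}, 3); got {coords.shape}"
            )
        if self.labels is not None and len(self.labels) != adj.shape[0]:
            raise InvalidInputError("labels length must match node count")
        object.__setattr__(self, "adjacency", adj.astype(np.int8))
        object.__setattr__(self, "coordinates", coords)

    # -- basic properties -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def density(self) -> float:
        n = self.n_nodes
        return self.n_edges / (n * (n - 1) / 2)

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=0).astype(np.int64)

    def edge_list(self) -> np.ndarray:
        """(m, 2) array of i < j edges, lexicographic order."""
        i, j = np.where(np.triu(self.adjacency, 1))
        return np.column_stack([i, j])

    def edge_lengths(self) -> np.ndarray:
        """Euclidean length of each existing edge (lexicographic order)."""
        edges = self.edge_list()
        if edges.size == 0:
            return np.empty(0)
        delta = self.coordinates[edges[:, 0]] - self.coordinates[edges[:, 1]]
        return np.linalg.norm(delta, axis=1)

    def distance_matrix(self) -> np.ndarray:
        return euclidean_distances(self.coordinates)

    def with_adjacency(self, adjacency: np.ndarray) -> "SpatialGraph":
        """New graph sharing this graph's embedding."""
        return SpatialGraph(adjacency, self.coordinates, self.labels)

    # -- I/O --------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Write the dense adjacency matrix as tab-delimited text."""
        np.savetxt(path, self.adjacency, fmt="%d", delimiter="\t")

    @classmethod
    def from_tsv(
        cls, adjacency_path: str | Path, coordinates_path: str | Path
    ) -> "SpatialGraph":
        adj = np.loadtxt(adjacency_path, delimiter="\t")
        coords = read_coordinates(coordinates_path)
        return cls(adj, coords.to_numpy())


def read_coordinates(path: str | Path) -> pd.DataFrame:
    """Read an (n, 3) coordinate table (columns x, y, z; optional header)."""
    df = pd.read_csv(path, sep="\t")
    cols = [c for c in ("x", "y", "z") if c in df.columns]
    if len(cols) == 3:
        return df[cols]
    return pd.read_csv(path, sep="\t", header=None, names=["x", "y", "z"])


def write_coordinates(coordinates: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(np.asarray(coordinates), columns=["x", "y", "z"]).to_csv(
        path, sep="\t", index=False
    )


@dataclass(frozen=True)
class WeightedStack:
    """Stack of weighted connectomes: (participants, n, n) streamline counts."""

    weights: np.ndarray = field()

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 3 or w.shape[1] != w.shape[2]:
            raise InvalidInputError(
                f"weights must be (participants, n, n); got {w.shape}"
            )
        if w.shape[0] == 0:
            raise InvalidInputError("stack must contain at least one participant")
        if np.any(w < 0):
            raise InvalidInputError("streamline counts must be non-negative")
        if not np.allclose(w, np.transpose(w, (0, 2, 1))):
            raise InvalidInputError("each slice must be symmetric")
        if np.any(w[:, np.arange(w.shape[1]), np.arange(w.shape[1])] != 0):
            raise InvalidInputError("each slice must have a zero diagonal")
        object.__setattr__(self, "weights", w)

    @property
    def n_participants(self) -> int:
        return self.weights.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[1]
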