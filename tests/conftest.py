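import numpy as np
import pytest

from wirecon import SpatialGraph, generate_coordinates


def graph_from_edges(n, edges, coord_seed=0):
    adj = np.zeros((n, n), dtype=int)
    for i, j in edges:
        adj[i, j] = adj[j, i] = 1
    return SpatialGraph(adj, generate_coordinates(n, coord_seed))


@pytest.fixture
def triangle():
    return graph_from_edges(3, [(0, 1), (1, 2), (0, 2)])


@pytest.fixture
def path3():
    """Path A-B-C."""
    return graph_from_edges(3, [(0, 1), (1, 2)])


@pytest.fixture
def two_triangles():
    return graph_from_edges(6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])


def random_graph(n, p, seed):
    rng = np.random.default_rng(seed)
    upper = np.triu(rng.random((n, n)) < p, 1).astype(int)
    return SpatialGraph(upper + upper.T, generate_coordinates(n, seed))


@pytest.fixture(scope="session")
def small_cohort():
    """30-node seed + a neighbours-rule target with known parameters."""
    from wirecon import GNMParams, generate_seed_graph, simulate

    coords = generate_coordinates(30, 42)
    seed = generate_seed_graph(coords, 0.10, 42)
    params = GNMParams(-3.0, 0.215)
    target = simulate(seed, 43, "neighbours", params, 777).final
    return {"seed": seed, "target": target, "params": params}
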