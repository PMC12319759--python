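"""The generative engine: value rules, wiring equation, simulation, grids."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wirecon import (
    GNMParams,
    SpatialGraph,
    build_grid,
    parameterised_nodal_terms,
    simulate,
    topological_value,
    wiring_probabilities,
)
from wirecon.errors import (
    InfeasibleTargetError,
    InvalidRuleError,
    InvalidSpecError,
    MissingTraceError,
    SaturatedGraphError,
)
from conftest import graph_from_edges, random_graph


class TestTopologicalValue:
    def test_identical_neighbourhoods_match_fully(self):
        # 0 and 1 both connect exactly to {2, 3} (and not each other)
        g = graph_from_edges(4, [(0, 2), (0, 3), (1, 2), (1, 3)])
        K = topological_value(g, "matching")
        assert K[0, 1] == pytest.approx(1.0)

    def test_disjoint_neighbourhoods(self):
        g = graph_from_edges(4, [(0, 2), (1, 3)])
        assert topological_value(g, "matching")[0, 1] == 0.0
        assert topological_value(g, "neighbours")[0, 1] == 0.0

    def test_matching_matches_brute_force_on_all_pairs(self):
        g = random_graph(5, 0.6, 3)
        K = topological_value(g, "matching")
        adj = np.asarray(g.adjacency)
        for i, j in itertools.combinations(range(5), 2):
            ni = set(np.flatnonzero(adj[i])) - {j}
            nj = set(np.flatnonzero(adj[j])) - {i}
            denom = len(ni) + len(nj)
            expected = 2 * len(ni & nj) / denom if denom else 0.0
            assert K[i, j] == pytest.approx(expected)

    def test_neighbours_is_shared_neighbour_count(self):
        g = random_graph(6, 0.5, 4)
        K = topological_value(g, "neighbours")
        adj = np.asarray(g.adjacency)
        for i, j in itertools.combinations(range(6), 2):
            assert K[i, j] == (adj[i] * adj[j]).sum()

    def test_spatial_rule_constant_and_average_rules(self):
        g = random_graph(6, 0.5, 5)
        K = topological_value(g, "spatial")
        off = ~np.eye(6, dtype=bool)
        assert (K[off] == 1.0).all()
        deg = g.degrees()
        Kd = topological_value(g, "degree_average")
        assert Kd[1, 2] == pytest.approx((deg[1] + deg[2]) / 2)

    def test_unknown_rule_rejected(self, triangle):
        with pytest.raises(InvalidRuleError):
            topological_value(triangle, "preferential")


class TestWiringProbabilities:
    def test_flat_landscape_is_uniform(self, path3):
        K = topological_value(path3, "neighbours")
        D = path3.distance_matrix()
        pairs, p = wiring_probabilities(K, D, path3, GNMParams(0.0, 0.0))
        np.testing.assert_allclose(p, np.full(len(p), 1 / len(p)))

    def test_distance_ratio_under_inverse_distance(self):
        # spatial rule, eta = -1: probability ratio = inverse distance ratio
        coords = np.array([[0, 0, 0], [1.0, 0, 0], [0, 2.0, 0], [5.0, 5, 5]])
        adj = np.zeros((4, 4), dtype=int)
        adj[0, 3] = adj[3, 0] = 1  # leaves (0,1) and (0,2) unconnected
        g = SpatialGraph(adj, coords)
        K = topological_value(g, "spatial")
        pairs, p = wiring_probabilities(
            K, g.distance_matrix(), g, GNMParams(-1.0, 0.7)
        )
        lookup = {tuple(pr): pi for pr, pi in zip(map(tuple, pairs), p)}
        # d(0,1) = 1, d(0,2) = 2 -> p(0,1)/p(0,2) = 2
        assert lookup[(0, 1)] / lookup[(0, 2)] == pytest.approx(2.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        eta=st.floats(-4, 4),
        gamma=st.floats(-2, 2),
        rule=st.sampled_from(["spatial", "matching", "neighbours",
                              "clustering_average", "degree_average"]),
    )
    def test_probabilities_always_normalised(self, seed, eta, gamma, rule):
        g = random_graph(10, 0.3, seed)
        if g.n_edges == 45:
            return
        K = topological_value(g, rule)
        _, p = wiring_probabilities(
            K, g.distance_matrix(), g, GNMParams(eta, gamma)
        )
        assert (p >= 0).all()
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_saturated_graph_rejected(self, triangle):
        K = topological_value(triangle, "spatial")
        with pytest.raises(SaturatedGraphError):
            wiring_probabilities(
                K, triangle.distance_matrix(), triangle, GNMParams(0, 0)
            )


class TestSimulate:
    def test_zero_additions_is_noop(self, triangle):
        trace = simulate(triangle, 3, "neighbours", GNMParams(-2, 0.2), 1)
        assert trace.added_edges == ()
        np.testing.assert_array_equal(trace.final.adjacency, triangle.adjacency)

    def test_strong_distance_penalty_picks_near_pair_first(self):
        # one near pair, distant others: eta = -10 makes it near-certain
        coords = np.array(
            [[0, 0, 0], [1.0, 0, 0], [60.0, 0, 0], [0, 60.0, 0]], dtype=float
        )
        g = SpatialGraph(np.zeros((4, 4), dtype=int), coords)
        wins = sum(
            simulate(g, 1, "spatial", GNMParams(-10.0, 0.0), k).added_edges[0]
            == (0, 1)
            for k in range(1000)
        )
        assert wins >= 990

    def test_bit_reproducible_for_fixed_seed(self, small_cohort):
        a = simulate(small_cohort["seed"], 43, "neighbours",
                     small_cohort["params"], 123)
        b = simulate(small_cohort["seed"], 43, "neighbours",
                     small_cohort["params"], 123)
        assert a.added_edges == b.added_edges

    def test_seed_preserved_and_no_duplicate_additions(self, small_cohort):
        trace = simulate(small_cohort["seed"], 43, "matching",
                         small_cohort["params"], 9)
        seed_adj = small_cohort["seed"].adjacency
        assert (trace.final.adjacency[seed_adj == 1] == 1).all()
        assert len(set(trace.added_edges)) == len(trace.added_edges)
        assert len(trace.added_edges) == 43 - small_cohort["seed"].n_edges

    def test_infeasible_targets_rejected(self, triangle):
        with pytest.raises(InfeasibleTargetError):
            simulate(triangle, 2, "spatial", GNMParams(0, 0), 0)
        with pytest.raises(InfeasibleTargetError):
            simulate(triangle, 4, "spatial", GNMParams(0, 0), 0)

    def test_mean_edge_length_decreases_with_distance_penalty(self):
        # spatial rule: |eta| up -> long edges penalised -> shorter networks
        from wirecon import generate_coordinates

        g = SpatialGraph(np.zeros((20, 20), dtype=int),
                         generate_coordinates(20, 8))
        means = []
        for eta in (0.0, -1.0, -2.0, -3.0):
            lengths = [
                simulate(g, 30, "spatial", GNMParams(eta, 0.0), 500 + k)
                .final.edge_lengths().mean()
                for k in range(100)
            ]
            means.append(np.mean(lengths))
        assert all(a >= b for a, b in zip(means, means[1:]))


class TestNodalTerms:
    def test_zero_eta_gives_degree_like_cost(self, small_cohort):
        trace = simulate(small_cohort["seed"], 43, "neighbours",
                         GNMParams(0.0, 0.2), 3, record=True)
        cost, _ = parameterised_nodal_terms(trace)
        np.testing.assert_allclose(cost, np.full(30, 29.0))

    def test_replay_oracle(self):
        """Nodal terms equal step-by-step recomputation from the edge trace."""
        g = random_graph(10, 0.25, 11)
        params = GNMParams(-2.0, 0.3)
        trace = simulate(g, g.n_edges + 8, "neighbours", params, 21,
                         record=True, record_probabilities=True)
        adj = np.asarray(g.adjacency, dtype=float).copy()
        D = g.distance_matrix()
        with np.errstate(divide="ignore"):
            Dp = D ** params.eta
        np.fill_diagonal(Dp, 0.0)
        value_acc = np.zeros(10)
        pair_acc = np.zeros(45)
        iu, ju = np.triu_indices(10, 1)
        for step, (i, j) in enumerate(trace.added_edges):
            current = SpatialGraph(adj.astype(int), g.coordinates)
            K = topological_value(current, "neighbours")
            Kp = (K + params.epsilon) ** params.gamma
            np.fill_diagonal(Kp, 0.0)
            value_acc += Kp.sum(axis=1)
            pairs, p = wiring_probabilities(K, D, current, params)
            step_p = np.zeros(45)
            for (a, b), pi in zip(map(tuple, pairs), p):
                idx = np.flatnonzero((iu == a) & (ju == b))[0]
                step_p[idx] = pi
            np.testing.assert_allclose(
                trace.probability_records[step], step_p, atol=1e-12
            )
            pair_acc += step_p
            adj[i, j] = adj[j, i] = 1
        cost, value = parameterised_nodal_terms(trace)
        np.testing.assert_allclose(cost, Dp.sum(axis=1))
        np.testing.assert_allclose(value, value_acc / 8)
        np.testing.assert_allclose(
            trace.mean_pair_probability, pair_acc / 8, atol=1e-12
        )

    def test_unrecorded_trace_rejected(self, small_cohort):
        trace = simulate(small_cohort["seed"], 43, "neighbours",
                         small_cohort["params"], 5)
        with pytest.raises(MissingTraceError):
            parameterised_nodal_terms(trace)


def test_trace_jsonl_round_trip(tmp_path, small_cohort):
    import json

    from wirecon.gnm import write_trace_jsonl

    trace = simulate(small_cohort["seed"], 43, "neighbours",
                     small_cohort["params"], 17, record=True,
                     record_probabilities=True)
    path = tmp_path / "run.trace"
    write_trace_jsonl(trace, path)
    lines = [json.loads(line) for line in path.read_text().splitlines()]
    header, records = lines[0], lines[1:]
    assert header["rule"] == "neighbours"
    assert header["final_edges"] == 43
    assert len(records) == len(trace.added_edges)
    assert [tuple(r["edge"]) for r in records] == list(trace.added_edges)
    assert all(0 < r["max_probability"] <= 1 for r in records)


class TestGrid:
    def test_printed_budget_counts(self):
        assert len(build_grid(100_000)) == 99_856  # 316 per axis
        assert len(build_grid(50_000)) == 49_729  # 223 per axis

    def test_tiny_budget_corners(self):
        grid = build_grid(4, (-1, 1), (-1, 1))
        assert {tuple(p) for p in grid} == {(-1, -1), (-1, 1), (1, -1), (1, 1)}

    def test_invalid_specs_rejected(self):
        with pytest.raises(InvalidSpecError):
            build_grid(0)
        with pytest.raises(InvalidSpecError):
            build_grid(10, (1, 1), (0, 1))


def test_params_validation():
    with pytest.raises(InvalidSpecError):
        GNMParams(np.inf, 0.0)
    with pytest.raises(InvalidSpecError):
        GNMParams(0.0, 0.0, epsilon=0.0)
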