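"""DCPM, L-statistic, null models and the Monte Carlo significance test."""

import numpy as np
import pytest

from dircp.graph import (
    BLOCK_MASK,
    DCPParams,
    DirectedGraph,
    Partition,
    mask_pair_count,
    sample_dcp,
)
from dircp.quality import (
    dcpm,
    l_statistic,
    monte_carlo_test,
    sample_config_null,
    sample_er_null,
)
from conftest import graph_from_edges, random_graph


def _dcpm_oracle(graph, partition):
    """Literal double-loop evaluation of the modularity sum."""
    n, m = graph.n, graph.m
    mean_a = m / n**2
    total = 0.0
    for u in range(n):
        for v in range(n):
            total += (graph.adjacency[u, v] - mean_a) * BLOCK_MASK[
                partition.labels[u], partition.labels[v]
            ]
    return total / m


class TestDCPM:
    def test_single_block_is_zero(self):
        graph = random_graph(6, 0.5, seed=0)
        for b in range(4):
            part = Partition(np.full(6, b))
            assert dcpm(graph, part) == pytest.approx(0.0, abs=1e-12)

    def test_perfect_l_small(self, perfect_small):
        graph, planted = perfect_small
        assert dcpm(graph, planted) == pytest.approx(1 - 20 / 64)

    def test_complement_of_perfect_l(self):
        sizes = (2, 2, 2, 2)
        graph, planted = sample_dcp(DCPParams(sizes, 1.0, 0.0), seed=0)
        comp = DirectedGraph(1 - graph.adjacency, graph.node_labels)
        got = dcpm(comp, planted)
        assert got == pytest.approx(-20 / 64)
        assert got == pytest.approx(_dcpm_oracle(comp, planted), abs=1e-12)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(1)
        for trial in range(10):
            n = int(rng.integers(3, 9))
            graph = random_graph(n, 0.5, seed=trial + 50)
            if graph.m == 0:
                continue
            part = Partition(rng.integers(0, 4, size=n))
            assert dcpm(graph, part) == pytest.approx(
                _dcpm_oracle(graph, part), abs=1e-12
            )

    def test_perfect_l_identity_random_sizes(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            sizes = tuple(int(x) for x in rng.integers(1, 8, size=4))
            graph, planted = sample_dcp(DCPParams(sizes, 1.0, 0.0), seed=3)
            n, m = graph.n, graph.m
            assert m == mask_pair_count(sizes)
            assert dcpm(graph, planted) == pytest.approx(1 - m / n**2, abs=1e-12)

    def test_edgeless_graph_rejected(self):
        with pytest.raises(ValueError):
            dcpm(graph_from_edges(4, []), Partition(np.zeros(4, dtype=int)))


class TestLStatistic:
    def test_perfect_structure_is_one(self, perfect_small):
        graph, planted = perfect_small
        assert l_statistic(graph, planted) == pytest.approx(1.0)

    def test_arithmetic_case(self):
        # E1=3, N1=4, E2=1, N2=12 (sizes (0,2,0,2), cf. likelihood test)
        g = graph_from_edges(4, [(0, 0), (0, 1), (1, 0), (0, 2)])
        part = Partition(np.array([1, 1, 3, 3]))
        assert l_statistic(g, part) == pytest.approx(0.75 - 1 / 12)

    def test_uniform_graph_centred_at_zero(self):
        part = Partition(np.repeat(np.arange(4), 10))
        stats = [
            l_statistic(random_graph(40, 0.3, seed=s), part) for s in range(50)
        ]
        assert abs(np.mean(stats)) < 0.02

    def test_degenerate_partition_flagged(self):
        graph = random_graph(5, 0.5, seed=0)
        with pytest.raises(ValueError):
            l_statistic(graph, Partition(np.zeros(5, dtype=int)))  # N1 = 0


class TestERNull:
    def test_saturated_case_fills_all_pairs(self):
        g = sample_er_null(5, 20, seed=0)
        assert g.m == 20
        assert np.trace(g.adjacency) == 0

    def test_exact_edge_count_and_no_loops(self):
        g = sample_er_null(50, 300, seed=1)
        assert g.m == 300
        assert np.trace(g.adjacency) == 0

    def test_uniform_pair_frequencies(self):
        reps = 50
        freq = np.zeros((100, 100))
        for s in range(reps):
            freq += sample_er_null(100, 500, seed=s).adjacency
        q = 500 / 9900
        sd = np.sqrt(q * (1 - q) * reps)
        off = ~np.eye(100, dtype=bool)
        # spot-check preselected ordered pairs at 4 binomial sd (a max over
        # all 9900 pairs would need a multiplicity-adjusted bound)
        pairs = [(0, 1), (1, 0), (5, 50), (99, 0), (42, 43), (7, 93)]
        for u, v in pairs:
            assert abs(freq[u, v] - reps * q) <= 4 * sd
        assert freq[off].sum() == reps * 500
        assert freq[~off].sum() == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sample_er_null(3, 10, seed=0)


class TestConfigNull:
    def test_degree_sequences_preserved(self):
        graph = random_graph(30, 0.2, seed=2)
        null = sample_config_null(graph, seed=3)
        assert np.array_equal(null.in_degrees, graph.in_degrees)
        assert np.array_equal(null.out_degrees, graph.out_degrees)
        assert null.m == graph.m

    def test_single_edge_graph_unchanged(self):
        graph = graph_from_edges(3, [(0, 1)])
        null = sample_config_null(graph, seed=0)
        assert np.array_equal(null.adjacency, graph.adjacency)

    def test_randomization_attenuates_planted_structure(self):
        diffs = []
        for seed in range(20):
            graph, planted = sample_dcp(
                DCPParams((25, 25, 25, 25), 0.6, 0.4), seed=seed
            )
            before = l_statistic(graph, planted)
            after = l_statistic(sample_config_null(graph, seed=seed + 1), planted)
            diffs.append(before - after)
        assert np.mean(diffs) > 0


class TestMonteCarlo:
    def test_p_value_floor_on_strong_structure(self, perfect_100):
        graph, _ = perfect_100
        res = monte_carlo_test(graph, "hits", null_model="er", replicates=19, seed=0)
        assert res.p_value == pytest.approx(1 / 20)
        assert res.observed_statistic == pytest.approx(1.0)
        assert res.replicates == 19

    def test_null_calibration_on_er_inputs(self):
        ps = []
        for s in range(20):
            graph = random_graph(60, 0.3, seed=200 + s)
            res = monte_carlo_test(graph, "hits", null_model="er", replicates=19, seed=s)
            ps.append(res.p_value)
        assert 0.2 < np.mean(ps) < 0.8

    def test_config_null_route(self, perfect_100):
        graph, _ = perfect_100
        res = monte_carlo_test(
            graph, "degree", null_model="config", replicates=9, seed=1
        )
        assert res.null_model == "config"
        assert 1 / 10 <= res.p_value <= 1.0

    def test_invalid_arguments_rejected(self, perfect_small):
        graph, _ = perfect_small
        with pytest.raises(ValueError):
            monte_carlo_test(graph, "nosuch", replicates=5, seed=0)
        with pytest.raises(ValueError):
            monte_carlo_test(graph, "hits", null_model="bogus", replicates=5, seed=0)
        with pytest.raises(ValueError):
            monte_carlo_test(graph, "hits", replicates=0, seed=0)
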