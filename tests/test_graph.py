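"""Block mask, DCP sampler and profile likelihood."""

import itertools

import numpy as np
import pytest

from dircp.graph import (
    BLOCK_MASK,
    BLOCK_NAMES,
    DCPParams,
    DirectedGraph,
    Partition,
    build_block_mask,
    mask_pair_count,
    planted_labels,
    profile_log_likelihood,
    sample_dcp,
)
from conftest import graph_from_edges


class TestBlockMask:
    def test_rows_match_l_structure(self):
        mask = build_block_mask()
        pout, cin, cout, pin = range(4)
        assert mask[cout].tolist() == [0, 1, 1, 1]  # Cout sends to Cin, itself, Pin
        assert mask[pin].tolist() == [0, 0, 0, 0]  # Pin never sends
        assert mask[pout].tolist() == [0, 1, 0, 0]  # Pout sends into Cin only
        assert mask[cin].tolist() == [0, 1, 0, 0]  # Cin internally dense only

    def test_exactly_five_ones(self):
        assert build_block_mask().sum() == 5

    @pytest.mark.parametrize("sizes", [(2, 2, 2, 2), (3, 1, 4, 2), (0, 5, 2, 7)])
    def test_pair_count_polynomial(self, sizes):
        a, b, c, d = sizes
        assert mask_pair_count(sizes) == a * b + b * b + c * b + c * c + c * d


class TestSampler:
    def test_idealized_sample_is_expanded_mask(self, perfect_small):
        graph, planted = perfect_small
        labels = planted_labels((2, 2, 2, 2))
        expected = BLOCK_MASK[np.ix_(labels, labels)]
        assert np.array_equal(graph.adjacency, expected)
        assert graph.m == 20
        assert np.array_equal(planted.labels, labels)

    def test_determinism(self):
        params = DCPParams((5, 5, 5, 5), 0.7, 0.2)
        g1, _ = sample_dcp(params, seed=123)
        g2, _ = sample_dcp(params, seed=123)
        assert np.array_equal(g1.adjacency, g2.adjacency)
        g3, _ = sample_dcp(params, seed=124)
        assert not np.array_equal(g1.adjacency, g3.adjacency)

    def test_edge_count_near_expectation(self):
        # E[m] = p1*N1 + p2*N2 for sizes (100,)*4: 0.6*50000 + 0.4*110000
        params = DCPParams((100, 100, 100, 100), 0.6, 0.4)
        graph, _ = sample_dcp(params, seed=5)
        n1 = mask_pair_count(params.sizes)
        n2 = 400**2 - n1
        expected = 0.6 * n1 + 0.4 * n2
        sd = np.sqrt(0.6 * 0.4 * n1 + 0.4 * 0.6 * n2)
        assert n1 == 50000 and expected == 74000
        assert abs(graph.m - expected) < 4 * sd

    def test_block_densities_converge(self):
        params = DCPParams((100, 100, 100, 100), 0.6, 0.4)
        on_rates, off_rates = [], []
        labels = planted_labels(params.sizes)
        on_l = BLOCK_MASK[np.ix_(labels, labels)].astype(bool)
        for seed in range(20):
            g, _ = sample_dcp(params, seed=seed)
            on_rates.append(g.adjacency[on_l].mean())
            off_rates.append(g.adjacency[~on_l].mean())
        assert abs(np.mean(on_rates) - 0.6) < 0.02
        assert abs(np.mean(off_rates) - 0.4) < 0.02

    @pytest.mark.parametrize("p1,p2", [(0.4, 0.5), (0.5, 0.5), (1.1, 0.0), (0.5, -0.1)])
    def test_invalid_probabilities_rejected(self, p1, p2):
        with pytest.raises(ValueError):
            DCPParams((2, 2, 2, 2), p1, p2)

    def test_empty_size_vector_rejected(self):
        with pytest.raises(ValueError):
            DCPParams((0, 0, 0, 0), 0.6, 0.4)


class TestGraphInvariants:
    def test_rejects_non_binary(self):
        with pytest.raises(ValueError):
            DirectedGraph(np.array([[0, 2], [0, 0]]), ("a", "b"))

    def test_rejects_duplicate_labels(self):
        with pytest.raises(ValueError):
            DirectedGraph(np.zeros((2, 2)), ("a", "a"))

    def test_reciprocated_pair_counts_twice(self):
        g = graph_from_edges(2, [(0, 1), (1, 0)])
        assert g.m == 2


class TestProfileLikelihood:
    def test_perfect_structure_has_zero_loglik(self, perfect_small):
        graph, planted = perfect_small
        ll, p1_hat, p2_hat = profile_log_likelihood(graph, planted)
        assert ll == 0.0
        assert p1_hat == 1.0
        assert p2_hat == 0.0

    def test_direct_arithmetic_case(self):
        # sizes (0, 2, 0, 2): N1 = nCin^2 = 4 on-mask ordered pairs, N2 = 12.
        # 3 edges inside Cin->Cin, 1 edge elsewhere => E1=3, E2=1.
        g = graph_from_edges(4, [(0, 0), (0, 1), (1, 0), (0, 2)])
        part = Partition(np.array([1, 1, 3, 3]))
        ll, p1_hat, p2_hat = profile_log_likelihood(g, part)
        expected = (
            3 * np.log(3 / 4)
            + np.log(1 / 4)
            + np.log(1 / 12)
            + 11 * np.log(11 / 12)
        )
        assert ll == pytest.approx(expected, abs=1e-12)
        assert ll == pytest.approx(-5.69, abs=0.005)
        assert p1_hat == pytest.approx(0.75)
        assert p2_hat == pytest.approx(1 / 12)

    def test_loglik_nonpositive_and_reorder_invariant(self):
        graph, planted = sample_dcp(DCPParams((3, 3, 3, 3), 0.9, 0.1), seed=2)
        ll, _, _ = profile_log_likelihood(graph, planted)
        assert ll <= 0.0
        rng = np.random.default_rng(0)
        for _ in range(5):
            perm = rng.permutation(graph.n)
            g2 = DirectedGraph(
                graph.adjacency[np.ix_(perm, perm)],
                tuple(graph.node_labels[i] for i in perm),
            )
            p2 = Partition(planted.labels[perm])
            ll2, _, _ = profile_log_likelihood(g2, p2)
            assert ll2 == pytest.approx(ll, abs=1e-9)

    def test_planted_beats_global_relabelings(self):
        # brute-force oracle: all 24 relabelings of the planted partition
        graph, planted = sample_dcp(DCPParams((3, 3, 3, 3), 0.9, 0.1), seed=4)
        ll_planted, _, _ = profile_log_likelihood(graph, planted)
        for perm in itertools.permutations(range(4)):
            relab = Partition(np.array(perm)[planted.labels])
            ll_perm, _, _ = profile_log_likelihood(graph, relab)
            assert ll_planted >= ll_perm - 1e-12

    def test_no_single_move_improves_perfect_structure(self):
        graph, planted = sample_dcp(DCPParams((3, 3, 3, 3), 1.0, 0.0), seed=0)
        ll0, _, _ = profile_log_likelihood(graph, planted)
        assert ll0 == 0.0
        for node in range(graph.n):
            for new in range(4):
                if new == planted.labels[node]:
                    continue
                moved = planted.labels.copy()
                moved[node] = new
                ll, _, _ = profile_log_likelihood(graph, Partition(moved))
                assert ll < 0.0

    def test_size_mismatch_rejected(self, perfect_small):
        graph, _ = perfect_small
        with pytest.raises(ValueError):
            profile_log_likelihood(graph, Partition(np.zeros(3, dtype=int)))


def test_partition_helpers():
    part = Partition.from_names(["Pout", "Cin", "Cout", "Pin", "Cin"])
    assert part.sizes.tolist() == [1, 2, 1, 1]
    assert part.names == ["Pout", "Cin", "Cout", "Pin", "Cin"]
    with pytest.raises(ValueError):
        Partition.from_names(["Core"])
    assert list(BLOCK_NAMES) == ["Pout", "Cin", "Cout", "Pin"]
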