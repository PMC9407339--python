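"""Heat kernel, Markov stability, Louvain optimization, VI, scales, MLS."""

import numpy as np
import pytest
import scipy.sparse as sp
from sympy.utilities.iterables import multiset_partitions

from sigsel import (
    CellGraph,
    ConstantSignalError,
    GeneSignalSet,
    GraphTopologyError,
    HeatKernel,
    Partition,
    heat_kernel,
    laplacian_score,
    markov_stability,
    mls,
    optimize_partition,
    scan_scales,
    stationary_distribution,
    variation_of_information,
)
from sigsel.multiscale import _select_vi_minima
from sigsel.synthetic import three_community_graph

from conftest import random_graph


def labels_from_blocks(blocks, n):
    lab = np.empty(n, dtype=int)
    for c, blk in enumerate(blocks):
        lab[list(blk)] = c
    return lab


class TestStationaryDistribution:
    def test_two_nodes(self):
        G = CellGraph.from_adjacency(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert np.allclose(stationary_distribution(G), [0.5, 0.5])

    def test_path_degree_proportional(self, path_graph):
        assert np.allclose(stationary_distribution(path_graph),
                           [0.25, 0.25, 0.5])

    def test_invariant_under_heat_kernel(self):
        G = random_graph(5, 8)
        pi = stationary_distribution(G)
        P = heat_kernel(G, 0.7).matrix
        assert np.allclose(pi @ P, pi, atol=1e-10)

    def test_disconnected_rejected(self):
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = A[2, 3] = A[3, 2] = 1.0
        G = CellGraph.from_adjacency(A)
        with pytest.raises(GraphTopologyError):
            stationary_distribution(G)


class TestHeatKernel:
    def test_time_zero_is_identity(self):
        G = random_graph(2, 7)
        assert np.allclose(heat_kernel(G, 0.0).matrix, np.eye(7), atol=1e-10)

    def test_two_node_closed_form(self):
        G = CellGraph.from_adjacency(np.array([[0.0, 1.0], [1.0, 0.0]]))
        t = 0.9
        a = (1 + np.exp(-2 * t)) / 2
        b = (1 - np.exp(-2 * t)) / 2
        assert np.allclose(heat_kernel(G, t).matrix, [[a, b], [b, a]], atol=1e-12)

    def test_semigroup_property(self):
        G = random_graph(7, 6)
        k = HeatKernel(G)
        assert np.allclose(k.matrix(0.3) @ k.matrix(0.5), k.matrix(0.8),
                           atol=1e-8)

    def test_detailed_balance(self):
        G = random_graph(8, 9)
        W = G.degrees[:, None] * HeatKernel(G).matrix(1.3)
        assert np.allclose(W, W.T, atol=1e-8)

    def test_long_time_limit_is_stationary(self):
        G = random_graph(9, 6)
        pi = stationary_distribution(G)
        assert np.allclose(heat_kernel(G, 1e4).matrix,
                           np.tile(pi, (6, 1)), atol=1e-8)

    def test_negative_time_rejected(self):
        G = random_graph(1, 4)
        with pytest.raises(ValueError):
            heat_kernel(G, -0.1)


class TestMarkovStability:
    def test_single_community_is_zero(self):
        G = random_graph(4, 8)
        part = Partition(np.zeros(8, dtype=int))
        for t in (0.0, 0.5, 3.0):
            assert markov_stability(G, part, t) == pytest.approx(0.0, abs=1e-12)

    def test_singletons_at_time_zero(self):
        G = random_graph(6, 7)
        pi = stationary_distribution(G)
        val = markov_stability(G, Partition(np.arange(7)), 0.0)
        assert val == pytest.approx(1 - float(pi @ pi), abs=1e-10)

    @pytest.mark.parametrize("seed", range(6))
    def test_range_over_exhaustive_partitions(self, seed):
        G = random_graph(seed + 60, 6)
        kernel = HeatKernel(G)
        for t in (0.1, 1.0, 10.0):
            for blocks in multiset_partitions(list(range(6))):
                val = markov_stability(
                    G, Partition(labels_from_blocks(blocks, 6)), t, kernel)
                assert -0.5 < val <= 1.0 + 1e-12

    def test_quality_matrix_form_equals_definition_sum(self):
        G = random_graph(13, 6)
        kernel = HeatKernel(G)
        pi = stationary_distribution(G)
        t = 0.8
        P = kernel.matrix(t)
        rng = np.random.default_rng(0)
        for _ in range(10):
            labels = rng.integers(0, 3, 6)
            direct = sum(
                pi[u] * P[u, v] - pi[u] * pi[v]
                for u in range(6) for v in range(6)
                if labels[u] == labels[v]
            )
            assert markov_stability(G, Partition(labels), t, kernel) == \
                pytest.approx(direct, abs=1e-12)


class TestOptimizePartition:
    def test_complete_graph_optimum_is_singletons_at_any_time(self, complete_graph):
        # All non-trivial eigenvalues of a complete graph coincide, so
        # stability = exp(-t*lambda) * (1 - sum_C pi_C^2): the singleton
        # partition is the exact maximizer at every finite time.
        for t in (0.5, 5.0):
            results = optimize_partition(complete_graph, t, runs=4, seed=1)
            for part, _val in results:
                assert part.n_communities == complete_graph.n_nodes

    def test_recovers_planted_three_communities(self):
        bundle = three_community_graph(seed=0)
        planted = Partition(bundle.truth["labels3"])
        results = optimize_partition(bundle.graph, 3.0, runs=5, seed=0)
        for part, _ in results:
            assert part.same_as(planted)

    def test_deterministic_given_seed(self):
        G = random_graph(21, 30)
        r1 = optimize_partition(G, 1.0, runs=3, seed=9)
        r2 = optimize_partition(G, 1.0, runs=3, seed=9)
        for (p1, v1), (p2, v2) in zip(r1, r2):
            assert np.array_equal(p1.labels, p2.labels)
            assert v1 == v2

    @pytest.mark.parametrize("t", [0.1, 1.0, 10.0])
    def test_matches_exhaustive_maximum_on_small_graphs(self, t):
        # Louvain is a heuristic: require >= 90% exact hits over trials
        hits = 0
        trials = 10
        for seed in range(trials):
            G = random_graph(seed + 200, 6)
            kernel = HeatKernel(G)
            best = max(
                markov_stability(G, Partition(labels_from_blocks(b, 6)), t, kernel)
                for b in multiset_partitions(list(range(6)))
            )
            found = max(v for _, v in optimize_partition(G, t, runs=5, seed=3,
                                                         kernel=kernel))
            assert found <= best + 1e-9
            hits += found >= best - 1e-9
        assert hits >= 0.9 * trials


class TestVariationOfInformation:
    def test_identical_partitions_zero(self):
        p = Partition(np.array([0, 0, 1, 2, 2]))
        q = Partition(np.array([2, 2, 0, 1, 1]))  # same up to relabeling
        assert variation_of_information(p, q) == pytest.approx(0.0)
        assert p.same_as(q)

    def test_singletons_vs_all_in_one_is_log2_n(self):
        n = 16
        p = Partition(np.arange(n))
        q = Partition(np.zeros(n, dtype=int))
        assert variation_of_information(p, q) == pytest.approx(np.log2(n))

    @pytest.mark.parametrize("seed", range(4))
    def test_metric_axioms(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        p, q, r = (Partition(rng.integers(0, 4, n)) for _ in range(3))
        dpq = variation_of_information(p, q)
        assert dpq == pytest.approx(variation_of_information(q, p))
        assert dpq >= 0
        assert dpq <= variation_of_information(p, r) + \
            variation_of_information(r, q) + 1e-12

    def test_mismatched_node_sets_rejected(self):
        with pytest.raises(ValueError):
            variation_of_information(Partition(np.zeros(3, int)),
                                     Partition(np.zeros(4, int)))


class TestScanScales:
    def test_three_community_fixture_selects_three_then_two(self):
        bundle = three_community_graph(seed=0)
        prof = scan_scales(bundle.graph, runs=8, seed=0)
        assert len(prof.selected_indices) >= 2
        coarse, coarsest = prof.selected_indices[-2:]
        assert prof.partitions[coarse].same_as(Partition(bundle.truth["labels3"]))
        assert prof.partitions[coarsest].same_as(Partition(bundle.truth["labels2"]))

    def test_flat_vi_on_complete_graph_falls_back_to_largest_time(
            self, complete_graph):
        times = np.logspace(-1, 1, 12)
        prof = scan_scales(complete_graph, times, runs=4, seed=0)
        assert list(prof.selected_indices) == [len(times) - 1]

    def test_plateau_midpoints_and_transition_filtering(self):
        vi = np.array([0.0, 0.0, 0.0, 0.0, 0.9, 0.0, 0.0, 0.0, 0.0, 0.0])
        k = np.array([8, 8, 8, 8, 5, 2, 2, 2, 2, 2])
        sel = _select_vi_minima(vi, k)
        assert list(sel) == [1, 7]  # plateau midpoints; spike/transition skipped

    def test_short_lived_states_are_not_scales(self):
        vi = np.zeros(12)
        k = np.array([9, 9, 9, 9, 9, 7, 3, 3, 3, 3, 3, 3])
        sel = _select_vi_minima(vi, k)
        assert list(sel) == [2, 8]  # the single-point k=7 state is skipped

    def test_runs_below_two_rejected(self):
        G = random_graph(2, 6)
        with pytest.raises(ValueError):
            scan_scales(G, np.array([0.1, 1.0]), runs=1, seed=0)


class TestMLS:
    def test_zero_at_time_zero(self):
        G = random_graph(31, 9)
        rng = np.random.default_rng(0)
        sigs = GeneSignalSet(["a", "b"], rng.standard_normal((2, 9)))
        M = mls(sigs, G, [0.0])
        assert np.allclose(M.scores, 0.0, atol=1e-10)

    def test_long_time_limit_is_one(self):
        G = random_graph(32, 8)
        rng = np.random.default_rng(1)
        sigs = GeneSignalSet(["a", "b", "c"], rng.standard_normal((3, 8)))
        M = mls(sigs, G, [1e4])
        assert np.allclose(M.scores, 1.0, atol=1e-6)

    def test_one_step_form_reproduces_laplacian_score(self):
        # replacing P(t) by the one-step matrix D^{-1} A in the MLS formula
        # recovers the classic Laplacian score exactly
        G = random_graph(33, 10)
        rng = np.random.default_rng(2)
        V = rng.standard_normal((4, 10))
        d = G.degrees
        W = G.adjacency.toarray()  # d_u * (D^{-1} A)_{uv} = A_{uv}
        mu = (V @ d) / d.sum()
        var = ((V - mu[:, None]) ** 2) @ d
        one_step = ((V**2 @ d) - np.einsum("gi,gi->g", V, V @ W)) / var
        ls = [laplacian_score(v, G) for v in V]
        assert np.allclose(one_step, ls, atol=1e-10)

    def test_constant_signal_rejected_with_name(self):
        G = random_graph(34, 6)
        sigs = GeneSignalSet(["flat"], np.ones((1, 6)))
        with pytest.raises(ConstantSignalError, match="flat"):
            mls(sigs, G, [1.0])

    def test_fixture_ordering_at_selected_scales(self):
        bundle = three_community_graph(seed=0)
        prof = scan_scales(bundle.graph, runs=8, seed=0)
        times = prof.times[prof.selected_indices[-2:]]
        M = mls(bundle.signals, bundle.graph, times)
        ids = list(M.gene_ids)
        largest = M.scores[ids.index("indicator_largest")]
        rand = M.scores[ids.index("random")]
        for j in range(2):
            col = M.scores[:, j]
            assert largest[j] == min(col)
            assert rand[j] == max(col)

    def test_monotone_in_time_for_community_indicator(self):
        bundle = three_community_graph(seed=0)
        ids = list(bundle.signals.gene_ids)
        sig = bundle.signals.subset([ids.index("indicator_largest")])
        times = np.logspace(0.5, 2, 8)  # beyond the community mixing scale
        M = mls(sig, bundle.graph, times)
        diffs = np.diff(M.scores[0])
        assert (diffs >= -1e-6).all()
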