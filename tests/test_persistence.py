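"""Filtrations, Kron reduction, persistent Betti-0, persistent Rayleigh quotients."""

import numpy as np
import pytest
import scipy.sparse as sp

from sigsel import (
    CellGraph,
    Filtration,
    FiltrationRangeError,
    SingularBlockError,
    ZeroSignalError,
    classify_bifurcation_role,
    filtered_subgraph,
    kron_reduce,
    laplacian,
    persistent_betti0,
    persistent_laplacian,
    prq,
    prq_map,
)
from sigsel.synthetic import toy_bifurcation

from conftest import random_graph


@pytest.fixture
def toy():
    return toy_bifurcation()


@pytest.fixture
def toy_filtration(toy):
    return Filtration(toy.truth["filtration"])


def random_filtration(rng, n, levels=3):
    return Filtration(rng.integers(0, levels, n))


class TestFiltration:
    def test_reverse_time_helper(self):
        f = Filtration.from_times([10, 11, 17, 13])
        assert np.array_equal(f.values, [7, 6, 0, 4])

    def test_sublevel_sets_nest(self):
        rng = np.random.default_rng(0)
        f = random_filtration(rng, 12, levels=5)
        prev = set()
        for i in range(f.min, f.max + 1):
            cur = set(f.sublevel(i).tolist())
            assert prev <= cur
            prev = cur
        assert len(prev) == 12

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            Filtration(np.array([0.5, 1.0]))


class TestFilteredSubgraph:
    def test_toy_alpha0_is_edgeless_with_two_components(self, toy, toy_filtration):
        alpha, sub = filtered_subgraph(toy.graph, toy_filtration, 0)
        assert list(toy.graph.node_ids[alpha]) == ["a", "b"]
        assert sub.adjacency.nnz == 0
        assert sub.n_components() == 2

    def test_saturation_returns_full_graph(self, toy, toy_filtration):
        _, sub = filtered_subgraph(toy.graph, toy_filtration, 99)
        assert sub.n_nodes == 3
        assert np.allclose(sub.adjacency.toarray(),
                           toy.graph.adjacency.toarray())

    def test_empty_sublevel_rejected(self, toy, toy_filtration):
        with pytest.raises(FiltrationRangeError):
            filtered_subgraph(toy.graph, toy_filtration, -1)


class TestKronReduce:
    def test_toy_reduction_is_half_weight_edge(self, toy):
        L = laplacian(toy.graph, "combinatorial")
        red = kron_reduce(L, [0, 1])
        assert np.allclose(red.matrix, [[0.5, -0.5], [-0.5, 0.5]], atol=1e-12)

    def test_full_subset_is_identity_operation(self):
        G = random_graph(40, 7)
        L = laplacian(G, "combinatorial").toarray()
        red = kron_reduce(L, np.arange(7))
        assert np.allclose(red.matrix, L)

    @pytest.mark.parametrize("seed", range(10))
    def test_lemma_properties_on_random_reductions(self, seed):
        # symmetry, zero row sums, non-positive off-diagonals -- checked on
        # 20 random subsets each of 10 random graphs (200 reductions)
        G = random_graph(seed + 70, 10)
        L = laplacian(G, "combinatorial").toarray()
        rng = np.random.default_rng(seed)
        for _ in range(20):
            m = rng.integers(2, 9)
            keep = np.sort(rng.choice(10, m, replace=False))
            red = kron_reduce(L, keep).matrix
            assert np.allclose(red, red.T, atol=1e-10)
            assert np.allclose(red @ np.ones(m), 0.0, atol=1e-10)
            off = red - np.diag(np.diag(red))
            assert off.max() <= 1e-12

    def test_schur_transitivity(self):
        G = random_graph(41, 9)
        L = laplacian(G, "combinatorial").toarray()
        alpha = np.array([0, 2, 3, 5, 6, 8])
        beta_in_alpha = np.array([0, 2, 4])  # positions within alpha
        via = kron_reduce(kron_reduce(L, alpha).matrix, beta_in_alpha).matrix
        direct = kron_reduce(L, alpha[beta_in_alpha]).matrix
        assert np.allclose(via, direct, atol=1e-9)

    def test_component_entirely_eliminated_is_singular(self):
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = A[2, 3] = A[3, 2] = 1.0
        G = CellGraph.from_adjacency(A)
        L = laplacian(G, "combinatorial")
        with pytest.raises(SingularBlockError):
            kron_reduce(L, [0, 1])  # the 2-3 component has no kept node


class TestPersistentLaplacian:
    def test_toy_01_matches_printed_reduction(self, toy, toy_filtration):
        red = persistent_laplacian(toy.graph, toy_filtration, 0, 1)
        assert np.allclose(red.matrix, [[0.5, -0.5], [-0.5, 0.5]], atol=1e-12)
        assert red.source == (0, 1)
        assert red.nullity() == 1

    def test_equal_indices_give_plain_laplacian(self, toy, toy_filtration):
        red = persistent_laplacian(toy.graph, toy_filtration, 1, 1)
        assert np.allclose(red.matrix,
                           laplacian(toy.graph, "combinatorial").toarray())

    def test_invalid_index_order_rejected(self, toy, toy_filtration):
        with pytest.raises(ValueError):
            persistent_laplacian(toy.graph, toy_filtration, 1, 0)


class TestPersistentBetti:
    def test_toy_merge(self, toy, toy_filtration):
        assert persistent_betti0(toy.graph, toy_filtration, 0, 1) == 1
        assert persistent_betti0(toy.graph, toy_filtration, 0, 0) == 2
        assert persistent_betti0(toy.graph, toy_filtration, 1, 1) == 1

    def test_two_cliques_without_merge(self):
        A = np.zeros((6, 6))
        A[:3, :3] = 1.0
        A[3:, 3:] = 1.0
        np.fill_diagonal(A, 0.0)
        G = CellGraph.from_adjacency(A)
        f = Filtration(np.array([0, 0, 1, 0, 0, 1]))
        assert persistent_betti0(G, f, 0, 1) == 2

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_numerical_nullity_of_persistent_laplacian(self, seed):
        # graph-theoretic count (connected components via union-find) vs
        # linear-algebraic nullity -- 10 valid filtrations each on 10 graphs
        # (draws where an entire component of G[alpha(j)] misses alpha(i)
        # are Kron-singular by definition and redrawn)
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 15))
        G = random_graph(seed + 300, n)
        checked = 0
        for _ in range(100):
            if checked >= 10:
                break
            f = random_filtration(rng, n, levels=4)
            i = int(rng.integers(f.min, f.max + 1))
            j = int(rng.integers(i, f.max + 1))
            try:
                red = persistent_laplacian(G, f, i, j)
            except SingularBlockError:
                continue
            assert red.nullity() == persistent_betti0(G, f, i, j)
            checked += 1
        assert checked == 10


class TestPRQ:
    def test_toy_table_matches_hand_computation(self, toy, toy_filtration):
        table, report = prq_map(toy.signals, toy.graph, toy_filtration,
                                [(0, 1), (1, 1)])
        assert report == []
        assert np.allclose(table["prq_0_1"], [0.0, 1.0, 0.0, 1.0], atol=1e-12)
        assert np.allclose(table["prq_1_1"], [0.0, 1 / 3, 1.0, 1.0], atol=1e-12)
        # above/below/on-diagonal sign pattern for (g1, g2, g3, g4)
        delta = table["prq_0_1"] - table["prq_1_1"]
        assert np.sign(np.round(delta, 12)).tolist() == [0.0, 1.0, -1.0, 0.0]

    def test_normalized_form_at_full_indices_matches_rayleigh(self, toy,
                                                              toy_filtration):
        from sigsel import rayleigh_quotient

        vals = prq(toy.signals, toy.graph, toy_filtration, 1, 1, normalized=True)
        expected = [rayleigh_quotient(v, toy.graph, normalized=True)
                    for v in toy.signals.values]
        assert np.allclose(vals, expected, atol=1e-12)

    def test_duplicate_pairs_give_identical_columns(self, toy, toy_filtration):
        table, _ = prq_map(toy.signals, toy.graph, toy_filtration,
                           [(0, 1), (0, 1)])
        assert table.shape[1] == 1 or np.allclose(table.iloc[:, 0],
                                                  table.iloc[:, -1])

    def test_zero_restricted_signal_flagged_not_dropped(self, toy,
                                                        toy_filtration):
        import numpy as np

        from sigsel import GeneSignalSet

        sigs = GeneSignalSet(["only_parent"], np.array([[0.0, 0.0, 1.0]]))
        table, report = prq_map(sigs, toy.graph, toy_filtration, [(0, 1)])
        assert np.isnan(table["prq_0_1"].iloc[0])
        assert report[0]["gene_id"] == "only_parent"
        with pytest.raises(ZeroSignalError, match="only_parent"):
            prq(sigs, toy.graph, toy_filtration, 0, 1)

    def test_quadrant_classifier_on_toy_values(self):
        full = np.array([0.0, 1 / 3, 1.0, 1.0])
        pers = np.array([0.0, 1.0, 0.0, 1.0])
        out = classify_bifurcation_role(full, pers)
        assert list(out) == ["constant", "parent+one-daughter",
                             "both-daughters", "single-daughter"]
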