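import networkx as nx
import numpy as np
import pytest

from _oracles import (
    graph_to_adj,
    oracle_centre,
    oracle_closest,
    oracle_kernel,
    oracle_rwr_linear,
    oracle_separation,
    oracle_shortest,
)
from conftest import random_connected_graph
from phytoscreen.interaction_features import (
    PropagationProblem,
    build_seed_vector,
    disease_score,
    fit_reduction,
    apply_reduction,
    node_index,
    normalize_adjacency,
    proximity_centre,
    proximity_closest,
    proximity_kernel,
    proximity_separation,
    proximity_shortest,
    rwr,
    rwr_closed_form,
)
from phytoscreen.io_core import CompoundProfile


class TestNormalizeAdjacency:
    def test_path_graph_degree_normalization(self, path_graph):
        W = normalize_adjacency(path_graph).toarray()
        # column of b (index 1) splits its mass halfway
        np.testing.assert_allclose(W[:, 1], [0.5, 0.0, 0.5])

    def test_isolated_node_zero_column(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        g.add_node("z")
        W = normalize_adjacency(g).toarray()
        assert (W[:, 2] == 0).all()

    def test_nonzero_columns_sum_to_one(self):
        g = random_connected_graph(np.random.default_rng(0), n_max=50)
        W = normalize_adjacency(g)
        sums = np.asarray(W.sum(axis=0)).ravel()
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)


class TestSeedVector:
    def test_single_direct_target(self, path_graph):
        idx = node_index(path_graph)
        p0, unmapped = build_seed_vector(CompoundProfile("c", {"a"}), idx)
        assert p0[idx["a"]] == 1.0 and p0.sum() == 1.0 and unmapped == 0

    def test_direct_indirect_ratio(self, path_graph):
        idx = node_index(path_graph)
        p0, _ = build_seed_vector(CompoundProfile("c", {"a"}, {"b"}), idx)
        assert p0[idx["a"]] == pytest.approx(1.0 / 1.3)
        assert p0[idx["b"]] == pytest.approx(0.3 / 1.3)

    def test_sums_to_one_and_counts_unmapped(self, path_graph):
        idx = node_index(path_graph)
        rng = np.random.default_rng(1)
        for _ in range(10):
            direct = set(rng.choice(["a", "b", "c", "x1"], size=2, replace=False))
            p0, unmapped = build_seed_vector(CompoundProfile("c", direct, {"x2"}), idx)
            assert p0.sum() == pytest.approx(1.0)
            assert unmapped == len((direct | {"x2"}) - set(idx))

    def test_empty_seed_errors(self, path_graph):
        with pytest.raises(ValueError, match="empty seed"):
            build_seed_vector(CompoundProfile("c", {"nope"}), node_index(path_graph))


class TestRwr:
    def test_single_node_self_loop_fixed_point(self):
        g = nx.Graph()
        g.add_edge("a", "a")  # degenerate: use explicit 1x1 operator instead
        import scipy.sparse as sp

        W = sp.csr_matrix(np.array([[1.0]]))
        p, its = rwr(PropagationProblem(W=W, p0=np.array([1.0]), r=0.3))
        np.testing.assert_allclose(p, [1.0])

    def test_two_node_edge_hand_elimination(self):
        # p = r(I - (1-r)Wᵀ)⁻¹p0 solved by hand for a single edge, r=0.7:
        # W = [[0,1],[1,0]] so p1 = 0.7 + 0.3 p2, p2 = 0.3 p1
        g = nx.Graph()
        g.add_edge("a", "b")
        W = normalize_adjacency(g)
        p0 = np.array([1.0, 0.0])
        p, _ = rwr(PropagationProblem(W=W, p0=p0, r=0.7))
        p1 = 0.7 / (1 - 0.09)
        np.testing.assert_allclose(p, [p1, 0.3 * p1], atol=1e-7)

    def test_matches_closed_form_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            g = random_connected_graph(rng, n_max=40)
            idx = node_index(g)
            p0 = np.zeros(len(idx))
            seeds = rng.choice(len(idx), size=3, replace=False)
            p0[seeds] = [0.5, 0.3, 0.2]
            problem = PropagationProblem(W=normalize_adjacency(g), p0=p0, r=0.7)
            p_iter, _ = rwr(problem)
            p_direct = oracle_rwr_linear(g, p0, 0.7)
            np.testing.assert_allclose(p_iter, p_direct, atol=1e-6)
            np.testing.assert_allclose(p_iter, rwr_closed_form(problem), atol=1e-6)
            assert (p_iter >= 0).all() and (p_iter <= 1).all()

    def test_iterations_decrease_with_restart_probability(self):
        g = random_connected_graph(np.random.default_rng(7), n_max=40)
        idx = node_index(g)
        p0 = np.zeros(len(idx))
        p0[0] = 1.0
        W = normalize_adjacency(g)
        iters = [
            rwr(PropagationProblem(W=W, p0=p0, r=r))[1] for r in (0.3, 0.5, 0.7, 0.9)
        ]
        assert all(a >= b for a, b in zip(iters, iters[1:]))

    def test_nonconvergence_raises_with_residual(self):
        g = nx.path_graph(4)
        g = nx.relabel_nodes(g, str)
        W = normalize_adjacency(g)
        p0 = np.array([1.0, 0, 0, 0])
        with pytest.raises(RuntimeError, match="residual"):
            rwr(PropagationProblem(W=W, p0=p0, r=0.1, tol=1e-16, max_iter=3))


class TestDiseaseScore:
    def test_all_nodes_is_total_mass(self, path_graph):
        idx = node_index(path_graph)
        p = np.array([0.5, 0.3, 0.2])
        assert disease_score(p, {"a", "b", "c"}, idx) == pytest.approx(1.0)

    def test_absent_genes_contribute_zero(self, path_graph):
        idx = node_index(path_graph)
        p = np.array([0.5, 0.3, 0.2])
        assert disease_score(p, {"a", "ghost"}, idx) == pytest.approx(0.5)

    def test_matches_indexed_sum(self, path_graph):
        rng = np.random.default_rng(3)
        idx = node_index(path_graph)
        p = rng.dirichlet(np.ones(3))
        genes = {"a", "c"}
        assert disease_score(p, genes, idx) == pytest.approx(
            sum(p[idx[g]] for g in genes)
        )


class TestReduction:
    def test_planar_data_needs_two_components(self):
        rng = np.random.default_rng(0)
        basis = rng.normal(size=(2, 10))
        coeffs = rng.normal(size=(50, 2)) @ np.diag([3.0, 2.0])
        X = coeffs @ basis
        model = fit_reduction(X, threshold=0.8)
        assert model.n_components == 2

    def test_threshold_one_keeps_rank(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 5)) @ rng.normal(size=(5, 8))
        model = fit_reduction(X, threshold=1.0)
        assert model.n_components == 5

    def test_reconstruction_error_equals_discarded_eigenvalues(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 6))
        model = fit_reduction(X, threshold=0.8)
        Z = apply_reduction(model, X)
        recon = Z @ model.components + model.center
        err = ((X - recon) ** 2).sum()
        # discarded eigenvalue mass, from an independent eigendecomposition
        C = np.cov(X, rowvar=False, ddof=1)
        eig = np.sort(np.linalg.eigvalsh(C))[::-1]
        discarded = eig[model.n_components :].sum() * (X.shape[0] - 1)
        assert err == pytest.approx(discarded, abs=1e-8)

    def test_stored_ratios_match_projected_variance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 7))
        model = fit_reduction(X, threshold=0.9)
        Z = apply_reduction(model, X)
        total = np.var(X - X.mean(axis=0), axis=0, ddof=1).sum()
        ratios = np.var(Z, axis=0, ddof=1) / total
        np.testing.assert_allclose(ratios, model.explained_variance_ratio, atol=1e-8)


class TestProximity:
    def test_closest_zero_when_targets_are_genes(self, path_graph):
        assert proximity_closest({"a", "b"}, {"a", "b", "c"}, path_graph) == 0.0

    def test_path_graph_hand_values(self, path_graph):
        assert proximity_closest({"a"}, {"c"}, path_graph) == 2.0
        assert proximity_shortest({"a"}, {"c"}, path_graph) == 2.0
        assert proximity_kernel({"a"}, {"c"}, path_graph) == pytest.approx(3.0)

    def test_kernel_same_node_singleton(self, path_graph):
        assert proximity_kernel({"a"}, {"a"}, path_graph) == pytest.approx(1.0)

    def test_centre_prefers_hub(self):
        g = nx.star_graph(5)
        g = nx.relabel_nodes(g, lambda i: "hub" if i == 0 else f"leaf{i}")
        assert proximity_centre({"leaf1"}, {"hub", "leaf2"}, g) == 1.0

    def test_separation_two_singletons(self, path_graph):
        assert proximity_separation({"a"}, {"c"}, path_graph) == 2.0

    def test_separation_nonpositive_when_sets_equal(self, path_graph):
        s = proximity_separation({"a", "b"}, {"a", "b"}, path_graph)
        assert s <= 0.0

    def test_disjoint_sets_error(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        with pytest.raises(ValueError):
            proximity_closest({"a"}, {"zz"}, g)

    @pytest.mark.parametrize("trial", range(25))
    def test_all_five_match_bfs_oracles(self, trial):
        rng = np.random.default_rng(100 + trial)
        g = random_connected_graph(rng, n_max=25)
        nodes = sorted(g.nodes)
        targets = set(rng.choice(nodes, size=int(rng.integers(1, 4)), replace=False))
        genes = set(rng.choice(nodes, size=int(rng.integers(1, 5)), replace=False))
        adj = graph_to_adj(g)
        assert proximity_closest(targets, genes, g) == pytest.approx(
            oracle_closest(adj, targets, genes)
        )
        assert proximity_shortest(targets, genes, g) == pytest.approx(
            oracle_shortest(adj, targets, genes)
        )
        assert proximity_kernel(targets, genes, g) == pytest.approx(
            oracle_kernel(adj, targets, genes)
        )
        assert proximity_centre(targets, genes, g) == pytest.approx(
            oracle_centre(adj, targets, genes)
        )
        assert proximity_separation(targets, genes, g) == pytest.approx(
            oracle_separation(adj, targets, genes)
        )
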