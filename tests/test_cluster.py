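"""Normalization, TF-IDF/LSI, neighbor graphs, Louvain and labelling."""

from __future__ import annotations

import numpy as np
import pytest
import scipy.sparse as sp

from pairedtag import cluster as cl
from pairedtag.errors import ConfigurationError, InputError


class TestNormalize:
    def test_scaling_identity(self):
        counts = np.zeros((1, 3))
        counts[0] = [10, 9_990, 0]
        norm = cl.normalize_rna(sp.csr_matrix(counts)).toarray()
        assert norm[0, 0] == pytest.approx(np.log1p(10.0))

    def test_all_zero_gene_stays_zero(self):
        counts = np.array([[5, 0], [3, 0]])
        norm = cl.normalize_rna(sp.csr_matrix(counts)).toarray()
        assert (norm[:, 1] == 0).all()

    def test_scale_invariance_per_cell(self):
        a = np.array([[1, 2, 3, 4]])
        b = 2 * a
        na = cl.normalize_rna(sp.csr_matrix(a)).toarray()
        nb = cl.normalize_rna(sp.csr_matrix(b)).toarray()
        np.testing.assert_allclose(na, nb, rtol=1e-12)

    def test_zero_total_cell_rejected(self):
        with pytest.raises(InputError):
            cl.normalize_rna(sp.csr_matrix(np.array([[0, 0], [1, 2]])))


class TestVariableGenes:
    def test_matches_brute_force_dispersion_ranking(self, rng):
        norm = sp.csr_matrix(rng.gamma(2.0, 1.0, size=(80, 40)))
        got = cl.select_variable_genes(norm, 10)
        dense = norm.toarray()
        mean = dense.mean(axis=0)
        var = dense.var(axis=0, ddof=1)
        disp = np.where(mean > 0, var / mean, 0.0)
        order = sorted(range(40), key=lambda j: (-disp[j], j))
        assert set(got.tolist()) == set(order[:10])

    def test_constant_genes_rank_last(self, rng):
        dense = rng.poisson(5.0, size=(50, 20)).astype(float)
        dense[:, 7] = 3.0  # constant -> zero variance
        got = cl.select_variable_genes(sp.csr_matrix(dense), 19)
        assert 7 not in got.tolist()

    def test_n_equals_all_genes_identity(self, rng):
        norm = sp.csr_matrix(rng.random((10, 8)))
        assert cl.select_variable_genes(norm, 8).tolist() == list(range(8))

    def test_oversized_n_warns_and_uses_all(self, rng):
        norm = sp.csr_matrix(rng.random((10, 8)))
        with pytest.warns(UserWarning):
            got = cl.select_variable_genes(norm, 20)
        assert got.tolist() == list(range(8))


def dense_tfidf(binary: np.ndarray, scale=1e4) -> np.ndarray:
    """Brute-force dense oracle for the TF-IDF variant."""
    n_cells = binary.shape[0]
    tf = binary / binary.sum(axis=1, keepdims=True)
    idf = n_cells / binary.sum(axis=0)
    return np.log1p(scale * tf * idf)


class TestTfidf:
    def test_matches_dense_oracle_small(self, rng):
        for _ in range(5):
            binary = (rng.random((7, 9)) < 0.5).astype(float)
            binary[binary.sum(axis=1) == 0, 0] = 1
            binary[:, binary.sum(axis=0) == 0] = 1
            got = cl.tfidf(sp.csr_matrix(binary)).toarray()
            np.testing.assert_allclose(got, dense_tfidf(binary), atol=1e-9)

    def test_three_by_four_hand_case(self):
        binary = np.array([[1, 1, 0, 0], [1, 0, 1, 0], [1, 0, 0, 1]], dtype=float)
        got = cl.tfidf(sp.csr_matrix(binary)).toarray()
        np.testing.assert_allclose(got, dense_tfidf(binary), atol=1e-9)
        # bin present in all cells has idf = 1, the minimal weight
        assert got[0, 0] == pytest.approx(np.log1p(1e4 * 0.5 * 1.0))

    def test_single_bin_cell_has_tf_one(self):
        binary = np.array([[0, 1], [1, 1]], dtype=float)
        got = cl.tfidf(sp.csr_matrix(binary)).toarray()
        assert got[0, 1] == pytest.approx(np.log1p(1e4 * 1.0 * (2 / 2)))

    def test_empty_row_or_column_rejected(self):
        with pytest.raises(InputError):
            cl.tfidf(sp.csr_matrix(np.array([[0, 0], [1, 1]], dtype=float)))
        with pytest.raises(InputError):
            cl.tfidf(sp.csr_matrix(np.array([[0, 1], [0, 1]], dtype=float)))


class TestReduce:
    def test_rank_one_matrix_first_component_dominates(self, rng):
        u = rng.random(40)
        v = rng.random(15)
        x = np.outer(u, v) + rng.normal(0, 1e-6, (40, 15))
        emb = cl.reduce(x, "pca", n=5, seed=0, scale=False)
        var = emb.coords.var(axis=0)
        assert var[0] / var.sum() > 0.999

    def test_lsi_drops_depth_component(self, rng):
        # cells with strongly varying depth: LSI component 1 tracks depth and
        # is dropped, decorrelating the retained embedding from cell totals
        depth = rng.gamma(4.0, 1.0, size=300)
        base = (rng.random((300, 120)) < 0.2 * depth[:, None] / depth.mean())
        base[base.sum(axis=1) == 0, 0] = True
        base = base[:, base.sum(axis=0) > 0]
        weighted = cl.tfidf(sp.csr_matrix(base.astype(float)))
        emb = cl.reduce(weighted, "lsi", n=10, seed=0)
        totals = base.sum(axis=1)
        r = np.corrcoef(emb.coords[:, 0], totals)[0, 1]
        assert emb.components == (2, 10)
        assert abs(r) < 0.35

    def test_embedding_reproducible(self, rng):
        x = rng.random((50, 20))
        a = cl.reduce(x, "pca", n=5, seed=3)
        b = cl.reduce(x, "pca", n=5, seed=3)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_rank_overflow_warns(self, rng):
        x = rng.random((6, 4))
        with pytest.warns(UserWarning):
            emb = cl.reduce(x, "pca", n=30, seed=0)
        assert emb.coords.shape[1] == 3

    def test_unknown_method_rejected(self):
        with pytest.raises(ConfigurationError):
            cl.reduce(np.eye(4), "tsne")


class TestKnnGraph:
    def test_no_cross_blob_edges(self, rng):
        a = rng.normal(0, 0.2, (40, 3))
        b = rng.normal(8, 0.2, (40, 3))
        coords = np.vstack([a, b])
        graph = cl.knn_graph(coords, k=10)
        cross = graph[:40, 40:]
        assert cross.nnz == 0
        # brute-force: nearest neighbours of every cell stay within its blob
        from scipy.spatial.distance import cdist

        d = cdist(coords, coords)
        for i in range(80):
            nn = np.argsort(d[i])[:11]
            assert ((nn < 40) == (i < 40)).all()

    def test_symmetry(self, rng):
        coords = rng.random((30, 4))
        graph = cl.knn_graph(coords, k=5)
        assert (abs(graph - graph.T) > 1e-12).nnz == 0

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(InputError):
            cl.knn_graph(rng.random((5, 2)), k=5)

    def test_collinear_triple_links_through_middle(self):
        coords = np.array([[0.0], [1.0], [2.0]])
        graph = cl.knn_graph(coords, k=1, prune=0.0)
        assert graph[0, 1] > 0 and graph[1, 2] > 0


class TestJointGraph:
    def test_limit_cases_and_symmetry(self, rng):
        g1 = cl.knn_graph(rng.random((25, 3)), k=4)
        g2 = cl.knn_graph(rng.random((25, 3)), k=4)
        assert (cl.joint_graph(g1, g2, 1.0) != g1).nnz == 0
        assert (cl.joint_graph(g1, g2, 0.0) != g2).nnz == 0
        ab = cl.joint_graph(g1, g2, 0.3)
        ba = cl.joint_graph(g2, g1, 0.7)
        assert abs(ab - ba).max() < 1e-12

    def test_mismatched_cells_rejected(self, rng):
        g1 = cl.knn_graph(rng.random((10, 2)), k=2)
        g2 = cl.knn_graph(rng.random((11, 2)), k=2)
        with pytest.raises(InputError):
            cl.joint_graph(g1, g2)


class TestClusterGraph:
    def _two_cliques(self, n=30):
        block = np.ones((n, n)) - np.eye(n)
        adj = np.zeros((2 * n, 2 * n))
        adj[:n, :n] = block
        adj[n:, n:] = block
        return sp.csr_matrix(adj)

    def test_two_disconnected_cliques(self):
        assign = cl.cluster_graph(self._two_cliques(), seed=0, min_size=10)
        assert assign.n_clusters == 2
        labels = assign.labels
        assert len(set(labels[:30])) == 1 and len(set(labels[30:])) == 1

    def test_low_resolution_single_cluster_on_connected_graph(self, rng):
        coords = rng.random((60, 2))
        graph = cl.knn_graph(coords, k=10)
        assign = cl.cluster_graph(graph, resolution=0.001, seed=0, min_size=10)
        assert assign.n_clusters == 1

    def test_small_clusters_flagged_excluded(self):
        adj = self._two_cliques(20)
        assign = cl.cluster_graph(adj, seed=0, min_size=50)
        assert assign.excluded == {0, 1}
        assert assign.retained_mask().sum() == 0

    def test_deterministic_under_seed(self, rng):
        graph = cl.knn_graph(rng.random((80, 3)), k=8)
        a = cl.cluster_graph(graph, seed=5, min_size=5)
        b = cl.cluster_graph(graph, seed=5, min_size=5)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_empty_graph_rejected(self):
        with pytest.raises(InputError):
            cl.cluster_graph(sp.csr_matrix((0, 0)))

    def test_leiden_backend_available(self):
        assign = cl.cluster_graph(self._two_cliques(), seed=0, min_size=10,
                                  backend="leiden")
        assert assign.n_clusters == 2


class TestLabels:
    def _setup(self, rng):
        # 3 clusters x 30 cells, marker blocks planted per type
        n = 90
        genes = [f"g{i}" for i in range(30)]
        x = rng.poisson(1.0, (n, 30)).astype(float)
        labels = np.repeat([0, 1, 2], 30)
        markers = {"alpha": ["g0", "g1"], "beta": ["g10", "g11"],
                   "gamma": ["g20", "g21"]}
        for c, genes_t in enumerate([(0, 1), (10, 11), (20, 21)]):
            for j in genes_t:
                x[labels == c, j] += 20
        assign = cl.ClusterAssignment(labels=labels, resolution=1.0, min_size=10)
        return x, genes, markers, assign

    def test_planted_types_labelled_correctly(self, rng):
        x, genes, markers, assign = self._setup(rng)
        assign = cl.label_clusters(assign, sp.csr_matrix(x), genes, markers)
        assert assign.type_labels == {0: "alpha", 1: "beta", 2: "gamma"}

    def test_scores_invariant_to_gene_order(self, rng):
        x, genes, markers, assign = self._setup(rng)
        s1 = cl.marker_scores(sp.csr_matrix(x), genes, assign, markers)
        perm = rng.permutation(30)
        s2 = cl.marker_scores(sp.csr_matrix(x[:, perm]),
                              [genes[j] for j in perm], assign, markers)
        np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-12)

    def test_signal_free_cluster_unresolved(self, rng):
        x, genes, markers, assign = self._setup(rng)
        markers["delta"] = ["g5"]
        x[:, 5] = 1.0  # flat gene: no cluster stands out
        labels4 = np.concatenate([assign.labels[:60], np.full(30, 3)])
        x2 = np.vstack([x[:60], rng.poisson(1.0, (30, 30))]).astype(float)
        assign2 = cl.ClusterAssignment(labels=labels4, resolution=1.0, min_size=10)
        assign2 = cl.label_clusters(assign2, sp.csr_matrix(x2), genes, markers,
                                    margin=0.5)
        assert assign2.type_labels[3] == "unresolved"

    def test_empty_marker_config_rejected(self, rng):
        x, genes, _markers, assign = self._setup(rng)
        with pytest.raises(ConfigurationError):
            cl.label_clusters(assign, sp.csr_matrix(x), genes, {})

    def test_doublet_cluster_flagged_pure_not(self, rng):
        x, genes, markers, assign = self._setup(rng)
        # make cluster 2 a 50/50 mixture of alpha and beta marker signal
        x[assign.labels == 2, 0:2] += 20
        x[assign.labels == 2, 10:12] += 20
        x[assign.labels == 2, 20:22] -= 20
        scores = cl.marker_scores(sp.csr_matrix(np.maximum(x, 0)), genes,
                                  assign, markers)
        flagged = cl.flag_doublet_clusters(assign, scores, threshold=0.5)
        assert 2 in flagged.doublet_flags
        assert 0 not in flagged.doublet_flags and 1 not in flagged.doublet_flags

    def test_infinite_threshold_flags_nothing(self, rng):
        x, genes, markers, assign = self._setup(rng)
        scores = cl.marker_scores(sp.csr_matrix(x), genes, assign, markers)
        assert cl.flag_doublet_clusters(assign, scores, np.inf).doublet_flags == set()
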