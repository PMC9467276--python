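"""Normalization, HVG selection, PCA, SNN graph and Louvain clustering."""

import numpy as np
import pytest
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score, silhouette_score

from balfkit.errors import ArgumentError, DegenerateInputError
from balfkit.io import CountMatrix
from balfkit.cluster import (
    ClusterPreset,
    EmbeddingMatrix,
    NeighborGraph,
    build_snn,
    cluster_counts,
    log_normalize,
    louvain_cluster,
    scale_and_pca,
    select_hvg_vst,
    subcluster,
    umap_embed,
)
from balfkit.simulate import simulate_balf

from conftest import two_subtype_config


def count_matrix(dense):
    n_genes, n_cells = dense.shape
    return CountMatrix(values=sp.csr_matrix(dense),
                       gene_ids=[f"g{i}" for i in range(n_genes)],
                       barcodes=[f"b{i}" for i in range(n_cells)])


def two_population_counts(seed=0, n_cells=300, n_genes=2000, n_shifted=50,
                          fold=8.0):
    """NB counts with ``n_shifted`` genes up-regulated in half the cells."""
    rng = np.random.default_rng(seed)
    base = rng.lognormal(0, 1, n_genes)
    rates = np.tile(base, (n_cells, 1))
    half = n_cells // 2
    rates[:half, :n_shifted] *= fold
    mu = rates / rates.sum(axis=1, keepdims=True) * 2500
    counts = rng.negative_binomial(10, 10 / (10 + mu))
    labels = np.repeat([0, 1], [half, n_cells - half])
    return count_matrix(counts.T), labels


class TestLogNormalize:
    def test_closed_form_values(self):
        dense = np.zeros((10_000, 1), dtype=int)
        dense[0, 0] = 1
        dense[1:, 0] = 1  # total 10^4
        m = count_matrix(dense)
        norm = log_normalize(m, scale_factor=1e4)
        assert norm.values[0, 0] == pytest.approx(np.log(2), abs=1e-12)

    def test_zero_counts_stay_zero(self, small_normalized):
        assert small_normalized.values.nnz == small_normalized.values.nnz
        assert (small_normalized.values.data > 0).all()

    def test_matches_dense_formula(self):
        rng = np.random.default_rng(1)
        dense = rng.integers(0, 5, size=(40, 30))
        dense[0, :] += 1  # no all-zero cells
        m = count_matrix(dense)
        norm = log_normalize(m, scale_factor=1e4)
        expected = np.log1p(dense * 1e4 / dense.sum(axis=0, keepdims=True))
        np.testing.assert_allclose(norm.values.toarray(), expected,
                                   rtol=1e-12)

    def test_zero_total_cell_names_barcode(self):
        dense = np.array([[1, 0], [2, 0]])
        m = count_matrix(dense)
        with pytest.raises(DegenerateInputError, match="b1"):
            log_normalize(m)


class TestHVG:
    def test_constant_gene_never_selected_over_varying(self):
        rng = np.random.default_rng(0)
        dense = rng.integers(0, 10, size=(50, 100))
        dense[0, :] = 3  # constant gene
        m = count_matrix(dense)
        hvg = select_hvg_vst(m, n_hvg=49)
        assert hvg.loc["g0", "variance_standardized"] == 0.0
        assert not hvg.loc["g0", "selected"]

    @pytest.mark.parametrize("seed", range(5))
    def test_planted_shifted_genes_rank_high(self, seed):
        m, _ = two_population_counts(seed, n_cells=400, n_genes=10_000)
        hvg = select_hvg_vst(m, n_hvg=2000)
        planted = [f"g{i}" for i in range(50)]
        assert hvg.loc[planted, "selected"].sum() >= 45

    def test_select_all_when_n_hvg_equals_n_genes(self):
        m, _ = two_population_counts(0, n_cells=100, n_genes=500)
        hvg = select_hvg_vst(m, n_hvg=500)
        assert hvg["selected"].all()
        # ranking is still a total order on standardized variance
        assert hvg["variance_standardized"].notna().all()

    def test_n_hvg_above_n_genes_warns(self):
        m, _ = two_population_counts(0, n_cells=50, n_genes=200)
        with pytest.warns(UserWarning, match="selecting all"):
            hvg = select_hvg_vst(m, n_hvg=1000)
        assert hvg["selected"].all()

    def test_bad_n_hvg_rejected(self, small_cohort):
        with pytest.raises(ArgumentError):
            select_hvg_vst(small_cohort[0], n_hvg=0)


class TestPCA:
    def embed(self, seed=0):
        m, labels = two_population_counts(seed)
        norm = log_normalize(m)
        hvg = select_hvg_vst(m, n_hvg=500)
        return scale_and_pca(norm, hvg, n_pcs=10), labels

    def test_variance_explained_non_increasing(self):
        emb, _ = self.embed()
        assert (np.diff(emb.variance_explained) <= 1e-9).all()

    def test_planted_populations_separate_on_pc1(self):
        emb, labels = self.embed()
        assert silhouette_score(emb.coords[:, :1], labels) >= 0.8

    def test_bitwise_determinism(self):
        a, _ = self.embed(3)
        b, _ = self.embed(3)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_excessive_n_pcs_rejected(self):
        m, _ = two_population_counts(0, n_cells=30, n_genes=100)
        norm = log_normalize(m)
        hvg = select_hvg_vst(m, n_hvg=50)
        with pytest.raises(ArgumentError):
            scale_and_pca(norm, hvg, n_pcs=40)


class TestSNN:
    def test_identical_neighbor_sets_give_weight_one(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(30, 3))
        coords[1] = coords[0]  # duplicate point: same k-NN set
        emb = EmbeddingMatrix(coords, np.ones(3),
                              [f"b{i}" for i in range(30)])
        graph = build_snn(emb, k=5, prune=0.0)
        assert graph.weights[0, 1] == pytest.approx(1.0)

    def test_knn_sets_match_brute_force(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(100, 5))
        emb = EmbeddingMatrix(coords, np.ones(5),
                              [f"b{i}" for i in range(100)])
        k = 10
        graph = build_snn(emb, k=k, prune=0.0)
        # brute-force oracle for the Jaccard weights
        d = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
        sets = [set(np.argsort(row, kind="stable")[:k]) for row in d]
        for i in range(0, 100, 7):
            for j in range(i + 1, 100, 13):
                inter = len(sets[i] & sets[j])
                expected = inter / (2 * k - inter)
                assert graph.weights[i, j] == pytest.approx(expected)

    def test_pruning_removes_weak_edges(self):
        rng = np.random.default_rng(2)
        coords = np.vstack([rng.normal(0, 0.1, size=(20, 2)),
                            rng.normal(100, 0.1, size=(20, 2))])
        emb = EmbeddingMatrix(coords, np.ones(2),
                              [f"b{i}" for i in range(40)])
        graph = build_snn(emb, k=5, prune=1 / 15)
        assert graph.weights[:20, 20:].nnz == 0  # disjoint neighbor sets

    def test_too_few_cells_rejected(self):
        emb = EmbeddingMatrix(np.zeros((5, 2)), np.ones(2),
                              [f"b{i}" for i in range(5)])
        with pytest.raises(ArgumentError):
            build_snn(emb, k=5)


class TestLouvain:
    def clique_graph(self):
        block = np.ones((10, 10)) - np.eye(10)
        W = sp.block_diag([block, block]).tocsr()
        return NeighborGraph(weights=W, k=9, prune=0.0,
                             barcodes=[f"b{i}" for i in range(20)])

    def test_two_disconnected_cliques_two_communities(self):
        labels = louvain_cluster(self.clique_graph(), resolution=1.0, seed=0)
        assert labels.n_clusters == 2
        assert len(set(labels.labels[:10])) == 1
        assert len(set(labels.labels[10:])) == 1

    def test_seeded_determinism(self, small_cohort):
        matrix, _ = small_cohort
        a = cluster_counts(matrix, n_pcs=10, resolution=1.0, seed=5)
        b = cluster_counts(matrix, n_pcs=10, resolution=1.0, seed=5)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_higher_resolution_never_fewer_communities(self, clean_cohort):
        matrix, _ = clean_cohort
        from balfkit.cluster import log_normalize as ln, select_hvg_vst as hv
        norm = ln(matrix)
        hvg = hv(matrix)
        emb = scale_and_pca(norm, hvg, n_pcs=10)
        graph = build_snn(emb)
        wins = 0
        for seed in range(20):
            lo = louvain_cluster(graph, resolution=0.5, seed=seed)
            hi = louvain_cluster(graph, resolution=2.0, seed=seed)
            wins += hi.n_clusters >= lo.n_clusters
        assert wins >= 19  # >= 95% of runs

    def test_labels_are_dense_and_size_ordered(self, clean_cohort):
        matrix, _ = clean_cohort
        labels = cluster_counts(matrix, n_pcs=10, resolution=1.0, seed=1)
        ids, counts = np.unique(labels.labels, return_counts=True)
        assert list(ids) == list(range(labels.n_clusters))
        assert (np.diff(counts) <= 0).all()


class TestSubcluster:
    def test_two_planted_subtypes_recovered(self):
        cfg = two_subtype_config(seed=4)
        matrix, truth = simulate_balf(cfg)
        labels = subcluster(matrix, np.arange(matrix.n_cells),
                            ClusterPreset(n_pcs=10, resolution=0.5), seed=4)
        ari = adjusted_rand_score(truth.cells["population"], labels.labels)
        assert ari >= 0.9

    def test_single_population_low_resolution_single_community(self):
        cfg = two_subtype_config(seed=5)
        matrix, truth = simulate_balf(cfg)
        only_a = (truth.cells["population"] == "sub_a").to_numpy()
        labels = subcluster(matrix, only_a,
                            ClusterPreset(n_pcs=5, resolution=0.1), seed=5)
        assert labels.n_clusters == 1

    def test_empty_subset_rejected(self, small_cohort):
        with pytest.raises(ArgumentError):
            subcluster(small_cohort[0], np.array([], dtype=int), "t_cell")

    def test_unknown_preset_rejected(self, small_cohort):
        with pytest.raises(ArgumentError, match="preset"):
            subcluster(small_cohort[0], np.arange(100), "nonsense")


class TestChainProperties:
    def test_permutation_equivariance(self, clean_cohort):
        matrix, _ = clean_cohort
        labels = cluster_counts(matrix, n_pcs=10, resolution=1.0, seed=2)
        rng = np.random.default_rng(0)
        perm = rng.permutation(matrix.n_cells)
        permuted = matrix.subset_cells(perm)
        labels_p = cluster_counts(permuted, n_pcs=10, resolution=1.0, seed=2)
        assert adjusted_rand_score(labels.labels[perm], labels_p.labels) == \
            pytest.approx(1.0)


class TestUMAP:
    def test_deterministic_and_separating(self):
        m, labels = two_population_counts(0, n_cells=120, n_genes=500)
        norm = log_normalize(m)
        hvg = select_hvg_vst(m, n_hvg=200)
        emb = scale_and_pca(norm, hvg, n_pcs=5)
        a = umap_embed(emb, seed=1)
        b = umap_embed(emb, seed=1)
        np.testing.assert_array_equal(a, b)
        centroid_gap = np.linalg.norm(
            a[labels == 0].mean(axis=0) - a[labels == 1].mean(axis=0))
        spread = np.mean([a[labels == g].std() for g in (0, 1)])
        assert centroid_gap > spread

    def test_too_few_cells_rejected(self):
        emb = EmbeddingMatrix(np.zeros((3, 2)), np.ones(2), ["a", "b", "c"])
        with pytest.raises(ArgumentError):
            umap_embed(emb)
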