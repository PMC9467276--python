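"""Module scoring, cell-cycle calls, marker detection and type assignment."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy import stats

from balfkit.errors import ArgumentError
from balfkit.io import NormalizedMatrix
from balfkit.cluster import ClusterLabels, log_normalize
from balfkit.annotate import (
    DEFAULT_MARKER_PANELS,
    _asymptotic_rank_sum_p,
    assign_major_types,
    cell_cycle_state,
    exact_rank_sum_p,
    find_all_markers,
    find_markers,
    module_score,
    score_group_test,
)


def normalized_from_dense(dense, symbols=None):
    n_genes, n_cells = dense.shape
    ids = [f"g{i}" for i in range(n_genes)]
    return NormalizedMatrix(
        values=sp.csr_matrix(dense), gene_ids=ids,
        gene_symbols=symbols or ids,
        barcodes=[f"b{i}" for i in range(n_cells)],
    )


def brute_force_rank_sum_p(x, y):
    """Literal enumeration over all group assignments (small n only)."""
    z = np.concatenate([x, y])
    n, n1 = len(z), len(x)
    r = stats.rankdata(z)
    mean_w = n1 * (n + 1) / 2.0
    dev = abs(r[:n1].sum() - mean_w)
    hits = total = 0
    for c in combinations(range(n), n1):
        total += 1
        hits += abs(r[list(c)].sum() - mean_w) >= dev - 1e-9
    return hits / total


class TestModuleScore:
    def test_exchangeable_genes_score_near_zero(self):
        rng = np.random.default_rng(0)
        dense = np.log1p(rng.poisson(2.0, size=(400, 200)).astype(float))
        norm = normalized_from_dense(dense)
        gene_set = [f"g{i}" for i in rng.choice(400, 25, replace=False)]
        score = module_score(norm, gene_set, seed=1)
        assert abs(score.mean()) < 0.05

    def test_planted_panel_separates_population(self, clean_normalized,
                                                clean_cohort):
        _, truth = clean_cohort
        planted_panel = truth.genes.loc[
            truth.genes["marker_of"] == "mo_ma", "symbol"].tolist()
        score = module_score(clean_normalized, planted_panel,
                             seed=2, name="mo_ma")
        is_mo = (truth.cells["population"] == "mo_ma").to_numpy()
        gap = score[is_mo].mean() - score[~is_mo].mean()
        null_spread = score[~is_mo].std()
        assert gap > 0
        assert gap > 3 * null_spread

    def test_absent_gene_set_rejected(self, clean_normalized):
        with pytest.raises(ArgumentError):
            module_score(clean_normalized, ["NOT_A_GENE"])

    def test_shift_invariance_within_bins(self):
        # adding a constant to all genes of the bin structure cancels out
        rng = np.random.default_rng(3)
        dense = np.log1p(rng.poisson(3.0, size=(120, 80)).astype(float))
        norm_a = normalized_from_dense(dense)
        score_a = module_score(norm_a, ["g5", "g17"], n_bins=1, seed=4)
        norm_b = normalized_from_dense(dense + 0.7)
        score_b = module_score(norm_b, ["g5", "g17"], n_bins=1, seed=4)
        np.testing.assert_allclose(score_a, score_b, atol=1e-9)

    def test_seed_reproducibility(self, clean_normalized):
        a = module_score(clean_normalized, DEFAULT_MARKER_PANELS["t_cell"],
                         seed=7)
        b = module_score(clean_normalized, DEFAULT_MARKER_PANELS["t_cell"],
                         seed=7)
        np.testing.assert_array_equal(a.to_numpy(), b.to_numpy())


class TestCellCycle:
    def build(self):
        # 3 cells: expresses only G2M genes / only S genes / neither
        dense = np.zeros((40, 3))
        dense[0:3, 0] = 2.0  # G2M genes in cell 0
        dense[3:6, 1] = 2.0  # S genes in cell 1
        rng = np.random.default_rng(0)
        dense[6:, :] = np.log1p(rng.poisson(1.0, size=(34, 3)))
        return normalized_from_dense(dense)

    def test_one_sided_dominance(self):
        norm = self.build()
        state = cell_cycle_state(norm, s_genes=["g3", "g4", "g5"],
                                 g2m_genes=["g0", "g1", "g2"], seed=0)
        assert state.iloc[0] == "cycling"
        assert state.iloc[1] == "resting"

    def test_empty_list_rejected(self):
        with pytest.raises(ArgumentError):
            cell_cycle_state(self.build(), [], ["g0"])

    def test_planted_cycling_fraction_recovered(self):
        rng = np.random.default_rng(5)
        n_cells, n_genes = 600, 300
        base = np.log1p(rng.poisson(1.0, size=(n_genes, n_cells)).astype(float))
        cycling = rng.random(n_cells) < 0.1
        g2m = list(range(10))
        s = list(range(10, 20))
        base[np.ix_(g2m, np.flatnonzero(cycling))] += 2.0
        base[np.ix_(s, np.flatnonzero(~cycling))] += 2.0
        norm = normalized_from_dense(base)
        state = cell_cycle_state(norm, [f"g{i}" for i in s],
                                 [f"g{i}" for i in g2m], seed=1)
        recovered = (state == "cycling").mean()
        assert abs(recovered - 0.1) <= 0.03


class TestFindMarkers:
    def two_group_norm(self, n_in=50, n_out=50, seed=0):
        rng = np.random.default_rng(seed)
        dense = np.log1p(rng.poisson(1.0, size=(100, n_in + n_out)))
        dense = dense.astype(float)
        dense[0, :n_in] = np.log1p(5.0)  # gene 0: on in-cluster only
        dense[0, n_in:] = 0.0
        norm = normalized_from_dense(dense)
        labels = ClusterLabels(
            labels=np.repeat([0, 1], [n_in, n_out]), resolution=1.0,
            barcodes=norm.barcodes)
        return norm, labels

    def test_perfectly_separating_gene(self):
        norm, labels = self.two_group_norm()
        table = find_markers(norm, labels, 0)
        row = table.set_index("gene").loc["g0"]
        assert row["pct.1"] == 1.0
        assert row["pct.2"] == 0.0
        assert row["p_val_adj"] < 1e-6
        assert row["avg_log2FC"] > 0

    def test_small_sample_p_matches_exact_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            x = rng.integers(0, 4, 8).astype(float)
            y = rng.integers(0, 5, 9).astype(float)
            assert exact_rank_sum_p(x, y) == \
                pytest.approx(brute_force_rank_sum_p(x, y), abs=1e-10)

    def test_exact_path_used_for_small_groups(self):
        norm, labels = self.two_group_norm(n_in=8, n_out=9, seed=3)
        table = find_markers(norm, labels, 0)
        row = table.set_index("gene").loc["g0"]
        x = np.full(8, np.log1p(5.0))
        y = np.zeros(9)
        assert row["p_val"] == pytest.approx(brute_force_rank_sum_p(x, y),
                                             abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_null_type_one_error_calibrated(self, seed):
        rng = np.random.default_rng(seed)
        dense = np.log1p(rng.negative_binomial(5, 5 / 7, size=(200, 2000)))
        in_mask = np.zeros(200, dtype=bool)
        in_mask[:100] = True
        p = _asymptotic_rank_sum_p(in_mask, dense.astype(float))
        assert abs((p < 0.05).mean() - 0.05) <= 0.02

    def test_empty_cluster_rejected(self):
        norm, labels = self.two_group_norm()
        with pytest.raises(ArgumentError):
            find_markers(norm, labels, 5)

    def test_bh_adjustment_monotone_and_bounded(self, clean_normalized,
                                                clean_cohort):
        _, truth = clean_cohort
        pops = truth.cells["population"].astype("category").cat.codes.to_numpy()
        labels = ClusterLabels(labels=pops, resolution=1.0,
                               barcodes=clean_normalized.barcodes)
        table = find_markers(clean_normalized, labels, 0)
        assert (table["p_val_adj"] >= table["p_val"] - 1e-15).all()
        ordered = table.sort_values("p_val")
        assert ordered["p_val_adj"].is_monotonic_increasing


class TestFindAllMarkers:
    def test_union_of_one_vs_rest(self, clean_normalized, clean_cohort):
        _, truth = clean_cohort
        two = (truth.cells["population"] == "t_cell").astype(int).to_numpy()
        labels = ClusterLabels(labels=two, resolution=1.0,
                               barcodes=clean_normalized.barcodes)
        table = find_all_markers(clean_normalized, labels)
        by_hand = pd.concat([
            find_markers(clean_normalized, labels, 0),
            find_markers(clean_normalized, labels, 1),
        ], ignore_index=True)
        pd.testing.assert_frame_equal(table, by_hand)

    def test_planted_markers_all_significant(self, clean_normalized,
                                             clean_cohort):
        _, truth = clean_cohort
        pops = truth.cells["population"]
        codes = pops.astype("category").cat.codes.to_numpy()
        labels = ClusterLabels(labels=codes, resolution=1.0,
                               barcodes=clean_normalized.barcodes)
        table = find_all_markers(clean_normalized, labels)
        cat = list(pops.astype("category").cat.categories)
        for ptype, panel in DEFAULT_MARKER_PANELS.items():
            cluster = cat.index(ptype)
            sub = table[(table["cluster"] == cluster)
                        & table["gene"].isin(panel)]
            assert len(sub) == len(panel)
            assert sub["significant"].all()

    def test_permuted_labels_yield_few_rejections(self, clean_normalized):
        rng = np.random.default_rng(8)
        fake = rng.integers(0, 2, clean_normalized.n_cells)
        labels = ClusterLabels(labels=fake, resolution=1.0,
                               barcodes=clean_normalized.barcodes)
        table = find_markers(clean_normalized, labels, 0, min_pct=0.0,
                             logfc_floor=-np.inf)
        assert (table["p_val"] < 0.05).mean() <= 0.05 + 0.02

    def test_single_cluster_rejected(self, clean_normalized):
        labels = ClusterLabels(
            labels=np.zeros(clean_normalized.n_cells, dtype=int),
            resolution=1.0, barcodes=clean_normalized.barcodes)
        with pytest.raises(ArgumentError):
            find_all_markers(clean_normalized, labels)


class TestAssignment:
    def test_planted_cohort_fully_assigned(self, clean_normalized,
                                           clean_cohort):
        _, truth = clean_cohort
        pops = truth.cells["population"]
        codes = pops.astype("category").cat.codes.to_numpy()
        labels = ClusterLabels(labels=codes, resolution=1.0,
                               barcodes=clean_normalized.barcodes)
        assignment = assign_major_types(clean_normalized, labels, seed=1)
        cat = list(pops.astype("category").cat.categories)
        for cluster, assigned in assignment.cluster_types.items():
            assert assigned == cat[cluster]

    def test_all_nonpositive_scores_unassigned(self):
        rng = np.random.default_rng(0)
        dense = np.log1p(rng.poisson(2.0, size=(60, 40)).astype(float))
        symbols = [f"g{i}" for i in range(60)]
        symbols[0], symbols[1] = "CD163", "CD68"
        dense[0:2, :] = 0.0  # panel genes silent everywhere
        norm = normalized_from_dense(dense, symbols)
        labels = ClusterLabels(labels=np.zeros(40, dtype=int), resolution=1.0,
                               barcodes=norm.barcodes)
        assignment = assign_major_types(
            norm, labels, panels={"mo_ma": ["CD163", "CD68"]}, seed=0)
        assert assignment.cluster_types[0] == "unassigned"

    def test_identical_panels_tie_to_unassigned(self, clean_normalized,
                                                clean_cohort):
        _, truth = clean_cohort
        is_t = (truth.cells["population"] == "t_cell").astype(int).to_numpy()
        labels = ClusterLabels(labels=is_t, resolution=1.0,
                               barcodes=clean_normalized.barcodes)
        panels = {"a": DEFAULT_MARKER_PANELS["t_cell"],
                  "b": DEFAULT_MARKER_PANELS["t_cell"]}
        with pytest.warns(UserWarning, match="margin"):
            assignment = assign_major_types(clean_normalized, labels,
                                            panels=panels, seed=0)
        assert assignment.cluster_types[1] == "unassigned"


class TestScoreGroupTest:
    def test_identical_observations_h_zero(self):
        h, p = score_group_test(pd.Series(np.ones(30)),
                                ["a"] * 10 + ["b"] * 20)
        assert h == 0.0

    def test_two_groups_agree_with_rank_sum(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        y = rng.normal(0.3, 1, size=35)
        _, p_kw = score_group_test(
            pd.Series(np.concatenate([x, y])), ["a"] * 40 + ["b"] * 35)
        _, p_w = stats.mannwhitneyu(x, y, alternative="two-sided",
                                    method="asymptotic", use_continuity=False)
        assert p_kw == pytest.approx(p_w, abs=1e-6)

    def test_null_rejection_rate_calibrated(self):
        rng = np.random.default_rng(2)
        rejections = 0
        n_rep = 1000
        groups = np.repeat(["a", "b", "c"], 30)
        for _ in range(n_rep):
            values = rng.normal(size=90)
            _, p = score_group_test(pd.Series(values), groups)
            rejections += p < 0.05
        assert abs(rejections / n_rep - 0.05) <= 0.02

    def test_empty_group_rejected(self):
        with pytest.raises(ArgumentError):
            score_group_test(pd.Series([1.0, 2.0]), ["a", "a"])
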