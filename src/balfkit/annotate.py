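"""Gene-set module scoring, cell-cycle calling, marker detection, typing.

Cluster annotation in a BALF cohort rests on canonical immune marker panels:
monocytes/macrophages (CD163, CD68), dendritic cells (CD83, CCR7, FSCN1),
T cells (CD2, CD3D, CD3E, CD3G), B/plasma cells (MS4A1, CD79A, CD79B),
neutrophils (TG, RGS2, LILRA5, CSF3R) and mast cells (LTC4S, HPGDS, GCSAML,
MS4A2). Each panel is scored per cell as the mean expression of the panel
genes minus the mean expression of control genes drawn from the same
average-expression bins, which cancels depth and baseline effects. Clusters
are assigned to the panel with the highest mean score, guarded by positivity
and a margin over the runner-up.

Marker genes per cluster are found one-vs-rest with a two-sided Wilcoxon
rank-sum test (tie-corrected normal approximation; exact distribution for
small groups) and Benjamini–Hochberg adjustment, with the conventional
significance gate of adjusted P < 0.05 and average log2 fold change > 0.25.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from balfkit.errors import ArgumentError
from balfkit.cluster import ClusterLabels
from balfkit.io import NormalizedMatrix

__all__ = [
    "DEFAULT_MARKER_PANELS",
    "CellTypeAssignment",
    "module_score",
    "cell_cycle_state",
    "find_markers",
    "find_all_markers",
    "assign_major_types",
    "score_group_test",
    "exact_rank_sum_p",
]

#: canonical marker panels for the six major BALF immune cell types
DEFAULT_MARKER_PANELS: dict[str, list[str]] = {
    "mo_ma": ["CD163", "CD68"],
    "dc": ["CD83", "CCR7", "FSCN1"],
    "t_cell": ["CD2", "CD3D", "CD3E", "CD3G"],
    "b_plasma": ["MS4A1", "CD79A", "CD79B"],
    "neutrophil": ["TG", "RGS2", "LILRA5", "CSF3R"],
    "mast": ["LTC4S", "HPGDS", "GCSAML", "MS4A2"],
}

SIG_ADJ_P = 0.05
SIG_LOG2FC = 0.25

DEG_COLUMNS = ["gene", "cluster", "p_val", "p_val_adj", "avg_log2FC",
               "pct.1", "pct.2", "significant"]


def _resolve_genes(normalized: NormalizedMatrix, gene_set,
                   what: str) -> np.ndarray:
    """Map symbols-or-ids to row indices; warn on absentees, error if none left."""
    lookup: dict[str, int] = {}
    for i, (gid, sym) in enumerate(zip(normalized.gene_ids,
                                       normalized.gene_symbols)):
        lookup.setdefault(sym, i)
        lookup.setdefault(gid, i)
    rows, missing = [], []
    for g in gene_set:
        if g in lookup:
            rows.append(lookup[g])
        else:
            missing.append(g)
    if missing:
        warnings.warn(
            f"{what}: {len(missing)} gene(s) not in matrix, dropped: "
            f"{missing[:5]}{'...' if len(missing) > 5 else ''}",
            stacklevel=3,
        )
    if not rows:
        raise ArgumentError(f"{what}: no gene of the set is present in the matrix")
    return np.array(rows)


# ---------------------------------------------------------------------------
# module score
# ---------------------------------------------------------------------------

def module_score(normalized: NormalizedMatrix, gene_set, n_bins: int = 24,
                 n_ctrl: int = 100, seed: int = 0,
                 name: str = "module") -> pd.Series:
    """Expression-bin-matched gene-set score per cell.

    All genes are ranked by mean expression across cells and split into
    ``n_bins`` equal-size bins. For each target gene, ``n_ctrl`` control
    genes are drawn from its bin (seeded; with replacement when the bin is
    smaller than ``n_ctrl``). The score is the mean expression of the target
    genes minus the mean expression of the drawn controls, per cell.
    """
    rows = _resolve_genes(normalized, gene_set, f"module_score({name})")
    X = normalized.values  # genes × cells, csr
    n_genes, n_cells = X.shape

    gene_mean = np.asarray(X.sum(axis=1)).ravel() / n_cells
    order = np.lexsort((np.arange(n_genes), gene_mean))
    rank = np.empty(n_genes, dtype=np.int64)
    rank[order] = np.arange(n_genes)
    bins = rank * n_bins // n_genes  # equal-size bins by mean-expression rank

    rng = np.random.default_rng(seed)
    bin_members = {b: np.flatnonzero(bins == b) for b in np.unique(bins)}
    ctrl_rows = []
    for r in rows:
        members = bin_members[bins[r]]
        replace = len(members) < n_ctrl
        ctrl_rows.append(rng.choice(members, size=n_ctrl, replace=replace))
    ctrl_rows = np.concatenate(ctrl_rows)

    target_mean = np.asarray(X[rows, :].mean(axis=0)).ravel()
    # controls keep multiplicity: repeated draws weigh their bin accordingly
    uniq, counts = np.unique(ctrl_rows, return_counts=True)
    weights = sp.csr_matrix(
        (counts / len(ctrl_rows), (np.zeros_like(uniq), uniq)),
        shape=(1, n_genes),
    )
    ctrl_mean = np.asarray((weights @ X).todense()).ravel()

    score = pd.Series(target_mean - ctrl_mean, index=normalized.barcodes,
                      name=name)
    score.attrs.update({"n_bins": n_bins, "n_ctrl": n_ctrl, "seed": seed})
    return score


def cell_cycle_state(normalized: NormalizedMatrix, s_genes, g2m_genes,
                     seed: int = 0, three_phase: bool = False) -> pd.Series:
    """Call each cell cycling (G2M) or resting (S) from two module scores.

    A cell is ``cycling`` iff its G2M score strictly exceeds its S score
    (ties resting). With ``three_phase=True`` cells whose two scores are both
    <= 0 are called ``g1`` instead.
    """
    if not list(s_genes) or not list(g2m_genes):
        raise ArgumentError("both S and G2M gene lists must be non-empty")
    s_score = module_score(normalized, s_genes, seed=seed, name="s_phase")
    g2m_score = module_score(normalized, g2m_genes, seed=seed + 1,
                             name="g2m_phase")
    state = np.where(g2m_score.to_numpy() > s_score.to_numpy(),
                     "cycling", "resting")
    if three_phase:
        neither = (s_score.to_numpy() <= 0) & (g2m_score.to_numpy() <= 0)
        state = np.where(neither, "g1", state)
    return pd.Series(state, index=normalized.barcodes, name="cycle_state")


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum machinery
# ---------------------------------------------------------------------------

def exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided rank-sum p-value under exchangeability, ties allowed.

    Computes P(|W - E[W]| >= |w - E[W]|) where W is the sum of the midranks
    assigned to the first group over all C(n, n1) assignments, via a
    generating-function DP on doubled midranks (always integral). Polynomial
    in n — no explicit enumeration of subsets.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n = len(x), len(x) + len(y)
    ranks = stats.rankdata(np.concatenate([x, y]))
    dr = np.round(ranks * 2).astype(np.int64)  # doubled midranks: integers
    w_obs = int(np.round(dr[:n1].sum()))
    total = int(dr.sum())

    # dp[k, s] = number of size-k subsets of dr with doubled-rank sum s
    dp = np.zeros((n1 + 1, total + 1), dtype=np.float64)
    dp[0, 0] = 1.0
    for r in dr:
        for k in range(n1, 0, -1):
            dp[k, r:] += dp[k - 1, : total + 1 - r]
    dist = dp[n1]
    n_subsets = dist.sum()

    mean_w = n1 * total / n
    dev = abs(w_obs - mean_w)
    support = np.flatnonzero(dist)
    extreme = np.abs(support - mean_w) >= dev - 1e-9
    return float(dist[support[extreme]].sum() / n_subsets)


def _asymptotic_rank_sum_p(in_mask: np.ndarray, dense: np.ndarray
                           ) -> np.ndarray:
    """Vectorized tie-corrected normal-approximation rank-sum p per column."""
    n, n_genes = dense.shape
    n1 = int(in_mask.sum())
    n2 = n - n1
    ranks = stats.rankdata(dense, axis=0)
    w = ranks[in_mask].sum(axis=0)
    mean_w = n1 * (n + 1) / 2.0

    # tie correction: sum(t^3 - t) over tie groups, per gene
    tie_term = np.zeros(n_genes)
    srt = np.sort(dense, axis=0)
    for j in range(n_genes):
        _, t = np.unique(srt[:, j], return_counts=True)
        tie_term[j] = np.sum(t.astype(float) ** 3 - t)
    var_w = (n1 * n2 / 12.0) * ((n + 1) - tie_term / (n * (n - 1.0)))
    var_w = np.maximum(var_w, 0.0)

    z = np.zeros(n_genes)
    ok = var_w > 0
    z[ok] = (w[ok] - mean_w) / np.sqrt(var_w[ok])
    p = 2.0 * stats.norm.sf(np.abs(z))
    p[~ok] = 1.0  # constant gene: no evidence either way
    return np.minimum(p, 1.0)


def find_markers(normalized: NormalizedMatrix, labels: ClusterLabels,
                 target_cluster: int, min_pct: float = 0.1,
                 logfc_floor: float = SIG_LOG2FC,
                 exact_max_n: int = 25) -> pd.DataFrame:
    """One-vs-rest differential expression for one cluster.

    Genes are pre-filtered to ``max(pct_in, pct_out) >= min_pct`` and
    ``avg_log2FC >= logfc_floor`` (positive markers), then tested with a
    two-sided Wilcoxon rank-sum (exact distribution when both groups have at
    most ``exact_max_n`` cells, tie-corrected normal approximation
    otherwise); BH adjustment runs over the tested genes.

    ``avg_log2FC = log2(mean(expm1(x_in)) + 1) - log2(mean(expm1(x_out)) + 1)``.
    """
    lab = np.asarray(labels.labels)
    in_mask = lab == target_cluster
    if in_mask.sum() == 0 or (~in_mask).sum() == 0:
        raise ArgumentError(
            f"cluster {target_cluster} or its complement is empty"
        )

    X = normalized.values.tocsc()  # genes × cells
    n_genes = X.shape[0]
    n_in = int(in_mask.sum())
    n_out = int((~in_mask).sum())

    Xin = X[:, np.flatnonzero(in_mask)]
    Xout = X[:, np.flatnonzero(~in_mask)]
    pct_in = np.asarray((Xin > 0).sum(axis=1)).ravel() / n_in
    pct_out = np.asarray((Xout > 0).sum(axis=1)).ravel() / n_out

    expm1_in = Xin.copy()
    expm1_in.data = np.expm1(expm1_in.data)
    expm1_out = Xout.copy()
    expm1_out.data = np.expm1(expm1_out.data)
    mean_in = np.asarray(expm1_in.sum(axis=1)).ravel() / n_in
    mean_out = np.asarray(expm1_out.sum(axis=1)).ravel() / n_out
    log2fc = np.log2(mean_in + 1.0) - np.log2(mean_out + 1.0)

    tested = np.flatnonzero(
        (np.maximum(pct_in, pct_out) >= min_pct) & (log2fc >= logfc_floor)
    )
    if tested.size == 0:
        return pd.DataFrame(columns=DEG_COLUMNS)

    dense = np.asarray(X[tested, :].todense()).T  # cells × tested genes
    if n_in <= exact_max_n and n_out <= exact_max_n:
        p = np.array([
            exact_rank_sum_p(dense[in_mask, j], dense[~in_mask, j])
            for j in range(dense.shape[1])
        ])
    else:
        p = _asymptotic_rank_sum_p(in_mask, dense)

    adj = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame({
        "gene": [normalized.gene_symbols[i] for i in tested],
        "cluster": target_cluster,
        "p_val": p,
        "p_val_adj": adj,
        "avg_log2FC": log2fc[tested],
        "pct.1": pct_in[tested],
        "pct.2": pct_out[tested],
    })
    out["significant"] = (out["p_val_adj"] < SIG_ADJ_P) & \
        (out["avg_log2FC"] > SIG_LOG2FC)
    return out.sort_values("p_val", kind="stable").reset_index(drop=True)


def find_all_markers(normalized: NormalizedMatrix, labels: ClusterLabels,
                     min_pct: float = 0.1, logfc_floor: float = SIG_LOG2FC
                     ) -> pd.DataFrame:
    """Concatenated one-vs-rest marker tables for every cluster."""
    clusters = np.unique(labels.labels)
    if clusters.size < 2:
        raise ArgumentError("need at least 2 clusters to find markers")
    tables = [
        find_markers(normalized, labels, int(c), min_pct=min_pct,
                     logfc_floor=logfc_floor)
        for c in clusters
    ]
    return pd.concat(tables, ignore_index=True) if tables else \
        pd.DataFrame(columns=DEG_COLUMNS)


# ---------------------------------------------------------------------------
# cluster → major-type assignment
# ---------------------------------------------------------------------------

@dataclass
class CellTypeAssignment:
    """Cluster-level major-type map plus the derived per-cell labels."""

    cluster_types: dict[int, str]
    cell_types: pd.Series  # barcode-indexed
    cluster_scores: pd.DataFrame  # clusters × panels mean module scores

    def type_counts(self) -> pd.Series:
        return self.cell_types.value_counts()


def assign_major_types(normalized: NormalizedMatrix, labels: ClusterLabels,
                       panels: dict[str, list[str]] | None = None,
                       seed: int = 0, margin: float = 0.05
                       ) -> CellTypeAssignment:
    """Assign each cluster to the marker panel with the highest mean score.

    A cluster is assigned its argmax panel only if that score is positive and
    beats the runner-up by ``margin``; otherwise it is ``unassigned``. Ties
    (e.g. two panels with identical gene lists) fall to the margin rule and
    produce ``unassigned`` with a warning.
    """
    if panels is None:
        panels = DEFAULT_MARKER_PANELS
    scores = pd.DataFrame({
        ptype: module_score(normalized, genes, seed=seed, name=ptype)
        for ptype, genes in panels.items()
    })
    lab = np.asarray(labels.labels)
    cluster_ids = np.unique(lab)
    cluster_means = pd.DataFrame(
        {c: scores[lab == c].mean(axis=0) for c in cluster_ids}
    ).T  # clusters × panels

    cluster_types: dict[int, str] = {}
    for c in cluster_ids:
        row = cluster_means.loc[c].sort_values(ascending=False)
        top, second = row.iloc[0], (row.iloc[1] if len(row) > 1 else -np.inf)
        if top > 0 and top - second > margin:
            cluster_types[int(c)] = str(row.index[0])
        else:
            cluster_types[int(c)] = "unassigned"
            if top > 0:
                warnings.warn(
                    f"cluster {c}: top panels within margin "
                    f"({row.index[0]}={top:.3f} vs {row.index[1]}={second:.3f});"
                    " left unassigned",
                    stacklevel=2,
                )

    cell_types = pd.Series(
        [cluster_types[int(c)] for c in lab],
        index=labels.barcodes, name="cell_type",
    )
    return CellTypeAssignment(cluster_types=cluster_types,
                              cell_types=cell_types,
                              cluster_scores=cluster_means)


def score_group_test(scores: pd.Series, groups) -> tuple[float, float]:
    """Kruskal–Wallis H test of a module score across >= 2 groups.

    ``groups`` is a per-cell label sequence aligned with ``scores``. Returns
    (H, p) with tie correction and a chi-square reference on k-1 degrees of
    freedom. All-identical observations give H = 0, p = 1.
    """
    groups = np.asarray(groups)
    values = np.asarray(scores)
    if groups.shape[0] != values.shape[0]:
        raise ArgumentError("groups and scores have different lengths")
    uniq = pd.unique(groups)
    if len(uniq) < 2:
        raise ArgumentError("need at least 2 groups")
    samples = [values[groups == g] for g in uniq]
    if any(len(s) == 0 for s in samples):
        raise ArgumentError("every group must be non-empty")
    if np.all(values == values[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), float(p)
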