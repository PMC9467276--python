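"""Normalization, HVG selection, PCA, SNN graph and Louvain clustering.

The chain mirrors the standard droplet scRNA-seq workflow: counts are
depth-normalized to 10,000 per cell and log1p-transformed; the 2,000 most
variable genes are selected by a variance-stabilizing transformation (a
local-regression trend of log variance on log mean, with standardized values
clipped at sqrt(n_cells)); the scaled HVG submatrix is embedded with PCA; a
shared-nearest-neighbor (SNN) graph connects cells by the Jaccard similarity
of their k-nearest-neighbor sets (each cell a member of its own set); and
communities are found by resolution-parameterized modularity (Louvain).

Sub-clustering presets re-run the whole chain on a cell subset. The shipped
presets are the ones appropriate for a BALF cohort: 16 PCs at resolution 1.0
for the full data, 13 PCs/1.2 for monocytes-macrophages, 11 PCs/0.5 for
T cells and 8 PCs/0.7 for B/plasma cells.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass

import igraph
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.nonparametric.smoothers_lowess import lowess

from balfkit.errors import ArgumentError, DegenerateInputError
from balfkit.io import CountMatrix, NormalizedMatrix

__all__ = [
    "CLUSTER_PRESETS",
    "ClusterPreset",
    "EmbeddingMatrix",
    "NeighborGraph",
    "ClusterLabels",
    "log_normalize",
    "select_hvg_vst",
    "scale_and_pca",
    "build_snn",
    "louvain_cluster",
    "cluster_counts",
    "subcluster",
    "umap_embed",
]


@dataclass(frozen=True)
class ClusterPreset:
    n_pcs: int
    resolution: float


#: number of PCs / clustering resolution per analysis context
CLUSTER_PRESETS: dict[str, ClusterPreset] = {
    "top_level": ClusterPreset(16, 1.0),
    "mo_ma": ClusterPreset(13, 1.2),
    "t_cell": ClusterPreset(11, 0.5),
    "b_plasma": ClusterPreset(8, 0.7),
}

DEFAULT_N_HVG = 2000
DEFAULT_K_NEIGHBORS = 20
DEFAULT_SNN_PRUNE = 1.0 / 15.0


@dataclass
class EmbeddingMatrix:
    """PCA coordinates (cells × n_pcs) with per-component explained variance."""

    coords: np.ndarray
    variance_explained: np.ndarray
    barcodes: list[str]

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]

    @property
    def n_pcs(self) -> int:
        return self.coords.shape[1]


@dataclass
class NeighborGraph:
    """Undirected SNN graph: symmetric sparse Jaccard weights, no self-loops."""

    weights: sp.csr_matrix
    k: int
    prune: float
    barcodes: list[str]

    @property
    def n_cells(self) -> int:
        return self.weights.shape[0]


@dataclass
class ClusterLabels:
    """Per-cell community ids (dense ints from 0, ordered by community size)."""

    labels: np.ndarray
    resolution: float
    barcodes: list[str]
    provenance: str = "top_level"

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "barcode": self.barcodes,
            "cluster": self.labels,
            "provenance": self.provenance,
        })


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def log_normalize(matrix: CountMatrix, scale_factor: float = 1e4
                  ) -> NormalizedMatrix:
    """Depth-normalize each cell to ``scale_factor`` counts and log1p.

    Entry = ln(1 + count * scale_factor / cell_total). Zero counts stay zero,
    preserving sparsity. An all-zero cell is a degenerate input (run QC
    first); the error names the offending barcode.
    """
    csc = matrix.values.tocsc()
    totals = np.asarray(csc.sum(axis=0)).ravel()
    if np.any(totals == 0):
        bad = matrix.barcodes[int(np.argmax(totals == 0))]
        raise DegenerateInputError(
            f"cell {bad!r} has zero total counts; filter cells before "
            "normalizing"
        )
    out = csc.astype(np.float64)
    # scale each column by scale_factor / total, then log1p in place
    out = out @ sp.diags(scale_factor / totals)
    out.data = np.log1p(out.data)
    return NormalizedMatrix(
        values=out, gene_ids=list(matrix.gene_ids),
        gene_symbols=list(matrix.gene_symbols),
        barcodes=list(matrix.barcodes), scale_factor=scale_factor,
    )


# ---------------------------------------------------------------------------
# HVG selection (variance-stabilizing transformation)
# ---------------------------------------------------------------------------

def select_hvg_vst(matrix: CountMatrix, n_hvg: int = DEFAULT_N_HVG,
                   trend_span: float = 0.3) -> pd.DataFrame:
    """Rank genes by variance of clipped standardized counts; flag the top.

    Per gene, the raw mean and variance are computed on counts; a lowess
    trend of log10(variance) on log10(mean) (span ``trend_span``) predicts
    the expected variance; counts are standardized by the predicted standard
    deviation, clipped at sqrt(n_cells); genes are ranked by the variance of
    those clipped values. Constant genes get standardized variance 0 and are
    never selected ahead of varying genes.

    Returns a gene-indexed DataFrame with columns ``mean``, ``variance``,
    ``variance_expected``, ``variance_standardized``, ``selected``.
    """
    if n_hvg <= 0:
        raise ArgumentError("n_hvg must be positive")
    n_genes, n_cells = matrix.values.shape
    if n_cells < 2:
        raise ArgumentError("need at least 2 cells for variance estimation")
    if n_hvg > n_genes:
        warnings.warn(
            f"n_hvg={n_hvg} exceeds the {n_genes} genes; selecting all",
            stacklevel=2,
        )
        n_hvg = n_genes

    X = matrix.values.tocsr().astype(np.float64)  # genes × cells
    mean = np.asarray(X.sum(axis=1)).ravel() / n_cells
    sq = X.copy()
    sq.data **= 2
    ex2 = np.asarray(sq.sum(axis=1)).ravel() / n_cells
    variance = (ex2 - mean ** 2) * n_cells / (n_cells - 1)
    variance = np.maximum(variance, 0.0)

    var_std = np.zeros(n_genes)
    expected = np.zeros(n_genes)
    varying = variance > 0
    if varying.any():
        lx = np.log10(mean[varying])
        ly = np.log10(variance[varying])
        fit = lowess(ly, lx, frac=trend_span, return_sorted=False)
        expected[varying] = 10.0 ** fit
        sd = np.sqrt(expected[varying])
        clip = np.sqrt(n_cells)

        # variance of clipped z-scores without densifying:
        # nonzero entries contribute min(z, clip)^2, zeros contribute z0^2
        mu_v = mean[varying]
        z0 = np.minimum((0.0 - mu_v) / sd, clip)
        idx_map = np.full(n_genes, -1)
        idx_map[np.flatnonzero(varying)] = np.arange(varying.sum())
        indptr, data = X.indptr, X.data
        ssq = np.zeros(varying.sum())
        nnz = np.zeros(varying.sum())
        rows = np.repeat(np.arange(n_genes), np.diff(indptr))
        keep = varying[rows]
        rv = idx_map[rows[keep]]
        z = np.minimum((data[keep] - mu_v[rv]) / sd[rv], clip)
        np.add.at(ssq, rv, z ** 2)
        np.add.at(nnz, rv, 1)
        var_std[varying] = (ssq + (n_cells - nnz) * z0 ** 2) / (n_cells - 1)

    order = np.lexsort((np.arange(n_genes), -var_std))  # stable, ties by index
    selected = np.zeros(n_genes, dtype=bool)
    selected[order[:n_hvg]] = True

    return pd.DataFrame({
        "gene_id": matrix.gene_ids,
        "mean": mean,
        "variance": variance,
        "variance_expected": expected,
        "variance_standardized": var_std,
        "selected": selected,
    }).set_index("gene_id")


# ---------------------------------------------------------------------------
# scaling and PCA
# ---------------------------------------------------------------------------

def scale_and_pca(normalized: NormalizedMatrix, hvg: pd.DataFrame,
                  n_pcs: int, clip: float = 10.0,
                  random_state: int = 0) -> EmbeddingMatrix:
    """Z-score the HVG submatrix per gene, clip, and embed with PCA.

    The sign of each component is fixed so its largest-magnitude gene loading
    is positive, making the embedding deterministic regardless of solver.
    """
    if n_pcs < 1:
        raise ArgumentError("n_pcs must be >= 1")
    sel = hvg["selected"].to_numpy()
    gene_rows = np.flatnonzero(
        pd.Index(normalized.gene_ids).isin(hvg.index[sel])
    )
    n_cells = normalized.n_cells
    if n_pcs > min(n_cells, len(gene_rows)):
        raise ArgumentError(
            f"n_pcs={n_pcs} exceeds min(n_cells={n_cells}, "
            f"n_hvg={len(gene_rows)})"
        )

    dense = np.asarray(normalized.values[gene_rows, :].todense(),
                       dtype=np.float64).T  # cells × genes
    mu = dense.mean(axis=0)
    sd = dense.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    scaled = (dense - mu) / sd
    np.clip(scaled, -clip, clip, out=scaled)

    solver = "arpack" if n_pcs < min(scaled.shape) else "full"
    pca = PCA(n_components=n_pcs, svd_solver=solver, random_state=random_state)
    coords = pca.fit_transform(scaled)

    # deterministic sign convention
    comp = pca.components_
    flip = comp[np.arange(n_pcs), np.abs(comp).argmax(axis=1)] < 0
    coords[:, flip] *= -1.0

    return EmbeddingMatrix(
        coords=coords,
        variance_explained=pca.explained_variance_.copy(),
        barcodes=list(normalized.barcodes),
    )


# ---------------------------------------------------------------------------
# SNN graph and community detection
# ---------------------------------------------------------------------------

def build_snn(embedding: EmbeddingMatrix, k: int = DEFAULT_K_NEIGHBORS,
              prune: float = DEFAULT_SNN_PRUNE) -> NeighborGraph:
    """Shared-nearest-neighbor graph with Jaccard weights.

    Each cell's k-nearest-neighbor set (exact Euclidean) includes the cell
    itself; edge weight between two cells is the Jaccard similarity of their
    sets, and edges with weight <= ``prune`` are removed.
    """
    n = embedding.n_cells
    if n <= k:
        raise ArgumentError(f"need more than k={k} cells, got {n}")
    nn = NearestNeighbors(n_neighbors=k).fit(embedding.coords)
    _, idx = nn.kneighbors(embedding.coords)
    # guarantee self-inclusion even under exact-duplicate ties
    idx[:, 0] = np.where((idx == np.arange(n)[:, None]).any(axis=1),
                         idx[:, 0], np.arange(n))

    indptr = np.arange(0, n * k + 1, k)
    A = sp.csr_matrix(
        (np.ones(n * k, dtype=np.int32), idx.ravel(), indptr), shape=(n, n)
    )
    inter = (A @ A.T).tocoo()
    jac = inter.data / (2.0 * k - inter.data)
    keep = (jac > prune) & (inter.row != inter.col)
    W = sp.csr_matrix((jac[keep], (inter.row[keep], inter.col[keep])),
                      shape=(n, n))
    W = W.maximum(W.T)  # numerically symmetric
    return NeighborGraph(weights=W, k=k, prune=prune,
                         barcodes=list(embedding.barcodes))


def _canonicalize_labels(membership: np.ndarray) -> np.ndarray:
    """Relabel communities by decreasing size, ties by lowest member index."""
    labels = np.asarray(membership)
    ids, counts = np.unique(labels, return_counts=True)
    first = np.array([np.argmax(labels == c) for c in ids])
    order = sorted(range(len(ids)), key=lambda i: (-counts[i], first[i]))
    remap = {ids[i]: rank for rank, i in enumerate(order)}
    return np.array([remap[v] for v in labels], dtype=np.int64)


def louvain_cluster(graph: NeighborGraph, resolution: float = 1.0,
                    seed: int = 0, provenance: str = "top_level"
                    ) -> ClusterLabels:
    """Louvain community detection on the SNN graph.

    Maximizes modularity under the resolution-parameterized
    configuration-model null. Isolated vertices become singleton communities.
    Seeded and reproducible: labels are identical across runs for a fixed
    seed. Vertices are processed in canonical barcode order, so permuting the
    input cells permutes the labels identically.
    """
    n = graph.n_cells
    if n == 0:
        raise ArgumentError("empty graph")
    order = np.argsort(np.asarray(graph.barcodes))  # canonical vertex order
    inv = np.empty(n, dtype=np.int64)
    inv[order] = np.arange(n)
    W = graph.weights[order][:, order]
    coo = sp.triu(W, k=1).tocoo()
    g = igraph.Graph(
        n=n, edges=list(zip(coo.row.tolist(), coo.col.tolist())),
        edge_attrs={"weight": coo.data.tolist()},
    )
    rng_state = random.getstate()
    try:
        random.seed(seed)  # python-igraph draws from Python's random module
        part = g.community_multilevel(weights="weight", resolution=resolution)
    finally:
        random.setstate(rng_state)
    labels = _canonicalize_labels(np.array(part.membership))[inv]
    return ClusterLabels(labels=labels, resolution=resolution,
                         barcodes=list(graph.barcodes), provenance=provenance)


# ---------------------------------------------------------------------------
# end-to-end helpers
# ---------------------------------------------------------------------------

def cluster_counts(matrix: CountMatrix, n_pcs: int, resolution: float,
                   seed: int = 0, n_hvg: int = DEFAULT_N_HVG,
                   k: int = DEFAULT_K_NEIGHBORS,
                   prune: float = DEFAULT_SNN_PRUNE,
                   scale_factor: float = 1e4,
                   provenance: str = "top_level") -> ClusterLabels:
    """Full chain: normalize → HVG → scale/PCA → SNN → Louvain."""
    normalized = log_normalize(matrix, scale_factor=scale_factor)
    hvg = select_hvg_vst(matrix, n_hvg=n_hvg)
    n_sel = int(hvg["selected"].sum())
    embedding = scale_and_pca(normalized, hvg,
                              n_pcs=min(n_pcs, n_sel, matrix.n_cells - 1),
                              random_state=seed)
    graph = build_snn(embedding, k=k, prune=prune)
    return louvain_cluster(graph, resolution=resolution, seed=seed,
                           provenance=provenance)


def subcluster(matrix: CountMatrix, cell_subset, preset, seed: int = 0,
               k: int = DEFAULT_K_NEIGHBORS, n_hvg: int = DEFAULT_N_HVG
               ) -> ClusterLabels:
    """Re-run the whole chain on a cell subset with a named or explicit preset.

    ``cell_subset`` is a boolean mask, an index array, or a list of barcodes;
    ``preset`` is a key of :data:`CLUSTER_PRESETS` or a
    :class:`ClusterPreset`. The subset must contain more than ``k`` cells.
    """
    if isinstance(preset, str):
        try:
            preset_obj = CLUSTER_PRESETS[preset]
        except KeyError:
            raise ArgumentError(
                f"unknown preset {preset!r}; options: {sorted(CLUSTER_PRESETS)}"
            ) from None
        name = preset
    else:
        preset_obj = preset
        name = "custom"

    subset = np.asarray(cell_subset)
    if subset.dtype.kind in ("U", "S", "O"):
        bc_index = {b: i for i, b in enumerate(matrix.barcodes)}
        subset = np.array([bc_index[b] for b in subset])
    elif subset.dtype == bool:
        subset = np.flatnonzero(subset)
    if subset.size <= k:
        raise ArgumentError(
            f"subset has {subset.size} cells; need more than k={k}"
        )
    sub = matrix.subset_cells(subset)
    return cluster_counts(sub, n_pcs=preset_obj.n_pcs,
                          resolution=preset_obj.resolution, seed=seed,
                          n_hvg=n_hvg, k=k, provenance=name)


def umap_embed(embedding: EmbeddingMatrix, seed: int = 0) -> np.ndarray:
    """2-D UMAP layout of the PCA embedding (visualization only)."""
    if embedding.n_cells < 4:
        raise ArgumentError("UMAP needs at least 4 cells")
    import umap  # deferred: numba compilation is slow to import

    reducer = umap.UMAP(n_components=2, random_state=seed)
    return reducer.fit_transform(embedding.coords)
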