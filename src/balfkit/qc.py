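"""Per-cell quality control.

Droplets containing ambient RNA, debris, or dying cells show up as barcodes
with few detected genes or a high mitochondrial fraction; droplets with far
more genes than expected are likely multiplets. Cells are removed when they
have fewer than ``min_genes`` detected genes, more than ``max_genes``, or a
mitochondrial percentage above ``max_pct_mito``. The removal rule uses strict
inequalities, so boundary cells (exactly 200 genes, exactly 15% mito) are
kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from balfkit.errors import ArgumentError
from balfkit.io import CountMatrix

__all__ = ["QCThresholds", "compute_qc_metrics", "filter_cells",
           "mito_genes_by_prefix"]

#: defaults for an equine BALF cohort
DEFAULT_MIN_GENES = 200
DEFAULT_MAX_GENES = 6500
DEFAULT_MAX_PCT_MITO = 15.0


@dataclass(frozen=True)
class QCThresholds:
    min_genes: int = DEFAULT_MIN_GENES
    max_genes: int = DEFAULT_MAX_GENES
    max_pct_mito: float = DEFAULT_MAX_PCT_MITO

    def __post_init__(self) -> None:
        if self.min_genes > self.max_genes:
            raise ArgumentError(
                f"min_genes ({self.min_genes}) > max_genes ({self.max_genes})"
            )
        if not 0 <= self.max_pct_mito <= 100:
            raise ArgumentError("max_pct_mito must be in [0, 100]")


def mito_genes_by_prefix(matrix: CountMatrix, prefix: str = "MT-") -> set[str]:
    """Gene ids whose symbol starts with ``prefix`` (case-insensitive)."""
    prefix = prefix.lower()
    return {gid for gid, sym in zip(matrix.gene_ids, matrix.gene_symbols)
            if sym.lower().startswith(prefix)}


def compute_qc_metrics(matrix: CountMatrix, mito_genes: set[str] | list[str]
                       ) -> pd.DataFrame:
    """Per-barcode QC metrics: ``n_genes``, ``total_counts``, ``pct_mito``.

    ``mito_genes`` are gene ids; members absent from the matrix are dropped
    with a warning. An all-zero cell gets (0, 0, 0.0) — it cannot survive the
    ``min_genes`` filter anyway.
    """
    mito_genes = set(mito_genes)
    known = set(matrix.gene_ids)
    missing = mito_genes - known
    if missing:
        warnings.warn(
            f"{len(missing)} mitochondrial gene id(s) not in matrix; dropped",
            stacklevel=2,
        )
        mito_genes &= known

    csc = matrix.values.tocsc()
    n_genes = np.diff(csc.indptr)  # nonzeros per cell column
    total = np.asarray(csc.sum(axis=0)).ravel()

    if mito_genes:
        gene_index = {g: i for i, g in enumerate(matrix.gene_ids)}
        rows = sorted(gene_index[g] for g in mito_genes)
        mito_total = np.asarray(csc[rows, :].sum(axis=0)).ravel()
    else:
        mito_total = np.zeros_like(total, dtype=float)

    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(total > 0, 100.0 * mito_total / np.maximum(total, 1), 0.0)

    return pd.DataFrame({
        "barcode": matrix.barcodes,
        "n_genes": n_genes.astype(int),
        "total_counts": total.astype(int),
        "pct_mito": pct,
    }).set_index("barcode")


def filter_cells(
    matrix: CountMatrix,
    metrics: pd.DataFrame,
    thresholds: QCThresholds | None = None,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Remove failing cells; return the filtered matrix and a full report.

    A cell is kept iff ``min_genes <= n_genes <= max_genes`` and
    ``pct_mito <= max_pct_mito``. The report covers every input barcode with
    columns (n_genes, total_counts, pct_mito, kept, reason); ``reason`` names
    the first violated criterion (min_genes, max_genes, max_pct_mito). The
    gene set is never changed, and filtering is idempotent.
    """
    if thresholds is None:
        thresholds = QCThresholds()
    if set(metrics.index) != set(matrix.barcodes):
        raise ArgumentError("metrics do not cover exactly the matrix barcodes")
    metrics = metrics.loc[matrix.barcodes]

    n_genes = metrics["n_genes"].to_numpy()
    pct_mito = metrics["pct_mito"].to_numpy()

    too_few = n_genes < thresholds.min_genes
    too_many = n_genes > thresholds.max_genes
    too_mito = pct_mito > thresholds.max_pct_mito
    kept = ~(too_few | too_many | too_mito)

    reason = np.full(len(kept), "", dtype=object)
    reason[too_mito] = "max_pct_mito"
    reason[too_many] = "max_genes"
    reason[too_few] = "min_genes"  # lowest-level failure wins the label

    report = metrics.copy()
    report["kept"] = kept
    report["reason"] = reason

    return matrix.subset_cells(kept), report
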