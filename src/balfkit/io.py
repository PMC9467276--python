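"""10x-style sparse count-matrix I/O and the core matrix containers.

The on-disk layout is the 10x Genomics convention: a Matrix Market
coordinate file (genes as rows, cells as columns) next to ``features.tsv``
and ``barcodes.tsv``, each optionally gzip-compressed. In memory the counts
live in a scipy CSR matrix; the dense matrix is never materialized.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from balfkit.errors import FormatError

__all__ = ["CountMatrix", "NormalizedMatrix", "read_10x_mtx", "write_10x_mtx"]


@dataclass
class CountMatrix:
    """Sparse non-negative integer gene×cell count matrix with labels.

    ``values`` has genes as rows and cells (barcodes) as columns, matching
    the 10x on-disk orientation. ``cells_by_genes()`` exposes the transposed
    view for per-cell computation.
    """

    values: sp.spmatrix
    gene_ids: list[str]
    gene_symbols: list[str] = field(default_factory=list)
    barcodes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        if not self.gene_symbols:
            self.gene_symbols = list(self.gene_ids)
        n_genes, n_cells = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise FormatError(
                f"matrix has {n_genes} rows but {len(self.gene_ids)} gene ids"
            )
        if len(self.gene_symbols) != n_genes:
            raise FormatError("gene_symbols length does not match gene_ids")
        if len(self.barcodes) != n_cells:
            raise FormatError(
                f"matrix has {n_cells} columns but {len(self.barcodes)} barcodes"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise FormatError("gene ids are not unique")
        if len(set(self.barcodes)) != n_cells:
            raise FormatError("barcodes are not unique")
        if self.values.nnz:
            data = self.values.data
            if np.any(data < 0):
                raise FormatError("negative entry in count matrix")
            if not np.issubdtype(data.dtype, np.integer) and \
                    not np.allclose(data, np.round(data)):
                raise FormatError("non-integer entry in count matrix")
        self.values.data = self.values.data.astype(np.int64, copy=False)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def cells_by_genes(self) -> sp.csr_matrix:
        """Counts as cells×genes CSR (the orientation used per-cell math)."""
        return sp.csr_matrix(self.values.T)

    def subset_cells(self, mask_or_indices) -> "CountMatrix":
        idx = np.asarray(mask_or_indices)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(
            values=self.values[:, idx],
            gene_ids=list(self.gene_ids),
            gene_symbols=list(self.gene_symbols),
            barcodes=[self.barcodes[i] for i in idx],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.gene_symbols == other.gene_symbols
            and self.barcodes == other.barcodes
            and self.values.shape == other.values.shape
            and (self.values != other.values).nnz == 0
        )


@dataclass
class NormalizedMatrix:
    """Log-normalized expression, same shape and labels as its source counts.

    Each entry is ``ln(1 + count * scale_factor / cell_total)``; zeros map
    to zero so sparsity is preserved.
    """

    values: sp.spmatrix  # genes × cells, float
    gene_ids: list[str]
    gene_symbols: list[str]
    barcodes: list[str]
    scale_factor: float = 1e4

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values, dtype=np.float64)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def cells_by_genes(self) -> sp.csr_matrix:
        return sp.csr_matrix(self.values.T)

    def subset_cells(self, mask_or_indices) -> "NormalizedMatrix":
        idx = np.asarray(mask_or_indices)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return NormalizedMatrix(
            values=self.values[:, idx],
            gene_ids=list(self.gene_ids),
            gene_symbols=list(self.gene_symbols),
            barcodes=[self.barcodes[i] for i in idx],
            scale_factor=self.scale_factor,
        )


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def _find(directory: Path, stem: str) -> Path:
    for name in (f"{stem}.tsv", f"{stem}.tsv.gz", f"{stem}.mtx", f"{stem}.mtx.gz"):
        p = directory / name
        if p.exists():
            return p
    raise FormatError(f"no {stem} file found in {directory}")


def _open_maybe_gzip(path: Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_10x_mtx(source) -> CountMatrix:
    """Read a 10x MTX triplet from a directory or a (mtx, features, barcodes) triple.

    Accepts plain or gzipped files. The Matrix Market header dimensions must
    match the features/barcodes files; negative or fractional entries are a
    :class:`FormatError`.
    """
    if isinstance(source, (tuple, list)):
        mtx_path, feat_path, bc_path = (Path(p) for p in source)
    else:
        directory = Path(source)
        if not directory.is_dir():
            raise FormatError(f"{directory} is not a directory")
        mtx_path = _find(directory, "matrix")
        try:
            feat_path = _find(directory, "features")
        except FormatError:
            feat_path = _find(directory, "genes")  # CellRanger v2 naming
        bc_path = _find(directory, "barcodes")

    with _open_maybe_gzip(mtx_path, "rb") as fh:
        try:
            mat = scipy.io.mmread(fh)
        except Exception as exc:  # noqa: BLE001 - surface as format error
            raise FormatError(f"cannot parse {mtx_path}: {exc}") from exc
    mat = sp.csr_matrix(mat)

    features = pd.read_csv(feat_path, sep="\t", header=None, dtype=str)
    if features.shape[1] < 1:
        raise FormatError(f"{feat_path} has no columns")
    gene_ids = features.iloc[:, 0].tolist()
    gene_symbols = (features.iloc[:, 1].tolist()
                    if features.shape[1] >= 2 else list(gene_ids))
    barcodes = pd.read_csv(bc_path, sep="\t", header=None,
                           dtype=str).iloc[:, 0].tolist()

    if mat.shape[0] != len(gene_ids):
        raise FormatError(
            f"matrix header says {mat.shape[0]} genes but features file has "
            f"{len(gene_ids)}"
        )
    if mat.shape[1] != len(barcodes):
        raise FormatError(
            f"matrix header says {mat.shape[1]} cells but barcodes file has "
            f"{len(barcodes)}"
        )
    return CountMatrix(values=mat, gene_ids=gene_ids,
                       gene_symbols=gene_symbols, barcodes=barcodes)


def write_10x_mtx(matrix: CountMatrix, directory, compress: bool = False) -> None:
    """Write the 10x MTX triplet into ``directory`` (created if needed).

    All-zero gene rows are preserved: the dimensions come from the labels,
    never from the stored entries.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    suffix = ".gz" if compress else ""

    coo = sp.coo_matrix(matrix.values)
    mtx_path = directory / f"matrix.mtx{suffix}"
    with _open_maybe_gzip(mtx_path, "wb") as fh:
        scipy.io.mmwrite(fh, coo, field="integer")

    with _open_maybe_gzip(directory / f"features.tsv{suffix}", "wt") as fh:
        for gid, sym in zip(matrix.gene_ids, matrix.gene_symbols):
            fh.write(f"{gid}\t{sym}\tGene Expression\n")
    with _open_maybe_gzip(directory / f"barcodes.tsv{suffix}", "wt") as fh:
        for bc in matrix.barcodes:
            fh.write(f"{bc}\n")


def convert_10x(src, dest, compress: bool) -> None:
    """Re-write an MTX triplet plain↔gzip."""
    write_10x_mtx(read_10x_mtx(src), dest, compress=compress)
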