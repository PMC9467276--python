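"""Synthetic BALF cohort generator with known ground truth.

Emulates the statistical structure of a droplet scRNA-seq experiment on
bronchoalveolar lavage fluid: six major immune populations in realistic
proportions, each with canonical panel markers plus a population-specific
signature program up-regulated a configurable fold; log-normal per-cell
sequencing depth; mitochondrial genes receiving a per-cell fraction of the
library; negative-binomial counts with shared dispersion; planted QC
failures (cells down-sampled below the detected-gene floor, cells re-weighted
to a high mitochondrial fraction); and heterotypic monocyte×T "complex"
doublets whose expression is the sum of two parents' programs.

Also provides a toy genome-annotation generator for exercising the 3'-UTR
extension stage, with a brute-force all-pairs overlap oracle computing which
transcripts must be blocked.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from balfkit.errors import ArgumentError
from balfkit.annotation import (
    AnnotationRecord,
    ExtensionPolicy,
    GenomeAnnotation,
    three_prime_extension_interval,
)
from balfkit.annotate import DEFAULT_MARKER_PANELS
from balfkit.io import CountMatrix

__all__ = [
    "PopulationSpec",
    "SimulationConfig",
    "GroundTruth",
    "default_balf_config",
    "qc_validation_config",
    "simulate_balf",
    "make_toy_annotation",
    "brute_force_blocked",
    "TABLE3_SCRNASEQ_DCC",
]

#: published scRNA-seq differential cell counts for the three-horse BALF
#: cohort (percentages per horse); the generator's default composition is
#: their mean.
TABLE3_SCRNASEQ_DCC: dict[str, tuple[float, float, float]] = {
    "lymphocytes": (85.3, 74.7, 71.3),
    "macrophages": (7.4, 13.7, 16.9),
    "neutrophils": (3.4, 10.5, 11.0),
    "mast_cells": (3.8, 1.1, 0.8),
    "eosinophils": (0.0, 0.0, 0.0),
}

#: the 13 protein-coding genes of the vertebrate mitochondrial genome
MITO_SYMBOLS = ["MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-ATP8", "MT-ATP6",
                "MT-CO3", "MT-ND3", "MT-ND4L", "MT-ND4", "MT-ND5", "MT-CYB",
                "MT-ND6"]


@dataclass(frozen=True)
class PopulationSpec:
    """One planted population: its share of cells and its up-regulated genes."""

    name: str
    fraction: float
    marker_genes: tuple[str, ...]
    marker_fold: float = 8.0
    parent_type: str | None = None

    def __post_init__(self) -> None:
        if self.fraction < 0:
            raise ArgumentError(f"population {self.name}: fraction < 0")
        if self.marker_fold <= 1:
            raise ArgumentError(f"population {self.name}: marker_fold must be > 1")


@dataclass(frozen=True)
class SimulationConfig:
    n_cells: int = 5000
    n_genes: int = 10000
    populations: tuple[PopulationSpec, ...] = ()
    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 1.0
    nb_dispersion: float = 10.0  # NB size; var = mu + mu^2/size
    depth_log_mean: float = float(np.log(2500.0))
    depth_log_sd: float = 0.35
    mito_gene_count: int = 13
    mito_fraction_mean: float = 0.04
    mito_fraction_sd: float = 0.015
    doublet_fraction: float = 0.02
    doublet_pairing: tuple[str, str] = ("mo_ma", "t_cell")
    qc_fail_low_genes: int = 0
    qc_fail_high_mito: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.populations:
            return
        total = sum(p.fraction for p in self.populations)
        if abs(total - 1.0) > 1e-6:
            raise ArgumentError(f"population fractions sum to {total}, not 1")
        if not 0 <= self.doublet_fraction < 1:
            raise ArgumentError("doublet_fraction must be in [0, 1)")
        n_planted = (self.qc_fail_low_genes + self.qc_fail_high_mito
                     + int(round(self.doublet_fraction * self.n_cells)))
        if n_planted > self.n_cells:
            raise ArgumentError(
                f"{n_planted} planted doublets/failures exceed "
                f"{self.n_cells} cells"
            )
        if self.mito_gene_count >= self.n_genes:
            raise ArgumentError("mito_gene_count must be < n_genes")


@dataclass
class GroundTruth:
    """Per-cell and per-gene truth tables for a simulated cohort."""

    cells: pd.DataFrame  # barcode-indexed: population, parent_type,
    #                      is_doublet, doublet_parents, planted_qc_failure
    genes: pd.DataFrame  # gene_id-indexed: symbol, is_mito, marker_of

    def singlet_mask(self) -> np.ndarray:
        return (~self.cells["is_doublet"]
                & (self.cells["planted_qc_failure"] == "")).to_numpy()


N_SIGNATURE_GENES = 30  # per-population program beyond the canonical panel


def _population_specs(marker_fold: float = 8.0) -> tuple[PopulationSpec, ...]:
    """Six populations at the mean of the published scRNA-seq proportions.

    Lymphocytes split 0.95 T : 0.05 B/plasma; macrophages split
    0.9 Mo/Ma : 0.1 DC. Each population carries its canonical panel plus
    a synthetic signature program of 30 genes at the same fold.
    """
    means = {cls: float(np.mean(v)) for cls, v in TABLE3_SCRNASEQ_DCC.items()}
    total = sum(means.values())
    cls_frac = {cls: v / total for cls, v in means.items()}
    fractions = {
        "t_cell": 0.95 * cls_frac["lymphocytes"],
        "b_plasma": 0.05 * cls_frac["lymphocytes"],
        "mo_ma": 0.9 * cls_frac["macrophages"],
        "dc": 0.1 * cls_frac["macrophages"],
        "neutrophil": cls_frac["neutrophils"],
        "mast": cls_frac["mast_cells"],
    }
    specs = []
    for name, frac in fractions.items():
        signature = tuple(f"{name}_sig{i:02d}" for i in range(N_SIGNATURE_GENES))
        specs.append(PopulationSpec(
            name=name, fraction=frac,
            marker_genes=tuple(DEFAULT_MARKER_PANELS[name]) + signature,
            marker_fold=marker_fold,
        ))
    return tuple(specs)


def default_balf_config(seed: int = 0) -> SimulationConfig:
    """The default BALF-like cohort: 5,000 cells × 10,000 genes.

    Composition follows the mean of the three published scRNA-seq
    differential cell counts; 2% monocyte×T doublets emulate
    monocyte–lymphocyte complexes; planted QC failures reproduce the study's
    observed failure rate (777/5,408 ≈ 14.4%), split evenly between
    low-gene and high-mito cells.
    """
    n_cells = 5000
    fail_total = int(round(n_cells * 777 / 5408))
    return SimulationConfig(
        n_cells=n_cells,
        populations=_population_specs(),
        qc_fail_low_genes=fail_total // 2,
        qc_fail_high_mito=fail_total - fail_total // 2,
        seed=seed,
    )


def qc_validation_config(seed: int = 0) -> SimulationConfig:
    """The QC-arithmetic cohort: 5,408 cells with exactly 777 planted failures."""
    return replace(default_balf_config(seed), n_cells=5408,
                   qc_fail_low_genes=389, qc_fail_high_mito=388)


# ---------------------------------------------------------------------------
# count simulation
# ---------------------------------------------------------------------------

def _gene_table(config: SimulationConfig) -> pd.DataFrame:
    """Fixed gene id/symbol layout: mito genes first, then markers, then bulk."""
    n = config.n_genes
    ids = [f"G{i:06d}" for i in range(n)]
    symbols = list(ids)
    is_mito = np.zeros(n, dtype=bool)
    marker_of = np.array([""] * n, dtype=object)

    n_mito = config.mito_gene_count
    for i in range(n_mito):
        symbols[i] = MITO_SYMBOLS[i] if i < len(MITO_SYMBOLS) else f"MT-G{i}"
        is_mito[i] = True

    cursor = n_mito
    for popn in config.populations:
        for sym in popn.marker_genes:
            if sym in symbols[:cursor]:  # shared marker: keep first owner
                continue
            if cursor >= n:
                raise ArgumentError("n_genes too small for the marker panels")
            symbols[cursor] = sym
            marker_of[cursor] = popn.name
            cursor += 1

    return pd.DataFrame({
        "gene_id": ids, "symbol": symbols,
        "is_mito": is_mito, "marker_of": marker_of,
    }).set_index("gene_id")


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, size_param: float
               ) -> np.ndarray:
    p = size_param / (size_param + mu)
    return rng.negative_binomial(size_param, p)


def simulate_balf(config: SimulationConfig
                  ) -> tuple[CountMatrix, GroundTruth]:
    """Draw one cohort; fixed seed gives bitwise-identical matrix and truth."""
    if not config.populations:
        raise ArgumentError("config has no populations")
    rng = np.random.default_rng(config.seed)
    n_cells, n_genes = config.n_cells, config.n_genes
    genes = _gene_table(config)
    mito_mask = genes["is_mito"].to_numpy()
    symbols = genes["symbol"].to_numpy()

    # baseline rates; marker/signature genes get a high baseline — canonical
    # markers (CD163, the CD3 complex, MS4A2...) are among the most abundant
    # transcripts of their cell types, not average genes
    base = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd,
                         n_genes)
    marked = genes["marker_of"].to_numpy() != ""
    base[marked] = rng.lognormal(config.baseline_log_mean + 2.0, 0.25,
                                 int(marked.sum()))

    sym_index = {s: i for i, s in enumerate(symbols)}
    pop_names = [p.name for p in config.populations]
    pop_rates = {}
    for popn in config.populations:
        r = base.copy()
        rows = [sym_index[g] for g in popn.marker_genes if g in sym_index]
        r[rows] *= popn.marker_fold
        pop_rates[popn.name] = r

    # per-cell assignments -------------------------------------------------
    fractions = np.array([p.fraction for p in config.populations])
    population = rng.choice(pop_names, size=n_cells, p=fractions)

    n_doublets = int(round(config.doublet_fraction * n_cells))
    order = rng.permutation(n_cells)
    doublet_idx = order[:n_doublets]
    low_idx = order[n_doublets:n_doublets + config.qc_fail_low_genes]
    mito_idx = order[n_doublets + config.qc_fail_low_genes:
                     n_doublets + config.qc_fail_low_genes
                     + config.qc_fail_high_mito]

    is_doublet = np.zeros(n_cells, dtype=bool)
    is_doublet[doublet_idx] = True
    qc_failure = np.array([""] * n_cells, dtype=object)
    qc_failure[low_idx] = "low_genes"
    qc_failure[mito_idx] = "high_mito"

    pa, pb = config.doublet_pairing
    if n_doublets and (pa not in pop_rates or pb not in pop_rates):
        raise ArgumentError(f"doublet_pairing {config.doublet_pairing} not in "
                            f"populations {pop_names}")
    population = population.astype(object)
    doublet_parents = np.array([""] * n_cells, dtype=object)
    population[doublet_idx] = "doublet"
    doublet_parents[doublet_idx] = f"{pa}+{pb}"

    depth = rng.lognormal(config.depth_log_mean, config.depth_log_sd, n_cells)
    depth[doublet_idx] *= 1.5  # two cells in one droplet
    depth[low_idx] = rng.uniform(60.0, 140.0, low_idx.size)  # < 200 genes

    mito_frac = rng.normal(config.mito_fraction_mean,
                           config.mito_fraction_sd, n_cells)
    mito_frac = np.clip(mito_frac, 0.005, 0.10)
    mito_frac[mito_idx] = rng.uniform(0.25, 0.35, mito_idx.size)  # > 15%

    # population probability profiles (non-mito part normalized to 1)
    profiles = {}
    for name, r in pop_rates.items():
        nm = r.copy()
        nm[mito_mask] = 0.0
        profiles[name] = nm / nm.sum()
    doublet_profile = pop_rates[pa] + pop_rates[pb] if n_doublets else None
    if doublet_profile is not None:
        doublet_profile = doublet_profile.copy()
        doublet_profile[mito_mask] = 0.0
        doublet_profile /= doublet_profile.sum()
    mito_profile = base * mito_mask
    mito_profile = mito_profile / mito_profile.sum()

    # counts, chunked over cells so the dense mean matrix stays small
    chunk = 512
    blocks = []
    for start in range(0, n_cells, chunk):
        stop = min(start + chunk, n_cells)
        idx = np.arange(start, stop)
        P = np.empty((idx.size, n_genes))
        for j, i in enumerate(idx):
            prof = doublet_profile if is_doublet[i] else profiles[population[i]]
            f = mito_frac[i]
            P[j] = (1.0 - f) * prof + f * mito_profile
        mu = P * depth[idx, None]
        counts = _nb_sample(rng, mu, config.nb_dispersion)
        blocks.append(sp.csr_matrix(counts.astype(np.int32)))
    counts_cells_by_genes = sp.vstack(blocks)

    barcodes = [f"CELL{i:05d}" for i in range(n_cells)]
    matrix = CountMatrix(
        values=counts_cells_by_genes.T.tocsr(),
        gene_ids=list(genes.index),
        gene_symbols=list(symbols),
        barcodes=barcodes,
    )

    parent_type = np.array(
        [next((p.parent_type or "" for p in config.populations
               if p.name == popname), "") if popname != "doublet" else ""
         for popname in population],
        dtype=object,
    )
    cells = pd.DataFrame({
        "barcode": barcodes,
        "population": population,
        "parent_type": parent_type,
        "is_doublet": is_doublet,
        "doublet_parents": doublet_parents,
        "planted_qc_failure": qc_failure,
    }).set_index("barcode")

    return matrix, GroundTruth(cells=cells, genes=genes)


# ---------------------------------------------------------------------------
# toy annotation generator + brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_blocked(annotation: GenomeAnnotation,
                        policy: ExtensionPolicy) -> set[str]:
    """O(n²) all-pairs oracle: transcripts whose extension hits another gene."""
    gene_spans = [(g.seqid, g.strand, g.start, g.end, g.id)
                  for g in annotation.genes()]
    blocked = set()
    for tx in annotation.transcripts():
        seqlen = annotation.sequence_lengths.get(tx.seqid)
        iv = three_prime_extension_interval(tx, policy.extension_length, seqlen)
        if iv is None:
            continue
        lo, hi = iv
        for seqid, strand, gs, ge, gid in gene_spans:
            if seqid != tx.seqid or gid == tx.parent:
                continue
            if policy.overlap_scope == "same-strand" and strand != tx.strand:
                continue
            if gs <= hi and ge >= lo:
                blocked.add(tx.id)
                break
    return blocked


def make_toy_annotation(n_genes: int = 40, n_seqs: int = 2,
                        overlap_fraction: float = 0.3, seed: int = 0,
                        extension_length: int = 2000
                        ) -> tuple[GenomeAnnotation, set[str]]:
    """Random toy gene models plus the truth set of blocked transcripts.

    Genes are laid out in pairs: a "colliding" pair (probability
    ``overlap_fraction``) sits closer than ``extension_length`` with the two
    genes facing each other, so both extensions are blocked; a clear pair is
    separated far beyond the extension on both sides. Pairs and sequences are
    separated widely. Truth is computed with the brute-force all-pairs
    overlap oracle, never by the extension implementation.
    """
    if not 0 <= overlap_fraction <= 1:
        raise ArgumentError("overlap_fraction must be in [0, 1]")
    if n_genes < 2:
        raise ArgumentError("need at least 2 genes")
    rng = np.random.default_rng(seed)
    records: list[AnnotationRecord] = []
    sequence_lengths: dict[str, int] = {}

    def add_gene(i: int, seqid: str, start: int, length: int, strand: str):
        end = start + length - 1
        gid, tid = f"gene{i}", f"tx{i}"
        records.append(AnnotationRecord(seqid, "gene", start, end, strand,
                                        gid, None, attributes=f"ID={gid}"))
        records.append(AnnotationRecord(seqid, "mRNA", start, end, strand,
                                        tid, gid, attributes=f"ID={tid}"))
        mid = start + length // 3
        records.append(AnnotationRecord(seqid, "exon", start, mid, strand,
                                        f"{tid}.e1", tid))
        records.append(AnnotationRecord(seqid, "exon", min(mid + 1, end), end,
                                        strand, f"{tid}.e2", tid))
        return end

    per_seq = -(-n_genes // n_seqs)  # ceil
    i = 0
    for s in range(n_seqs):
        seqid = f"chr{s + 1}"
        pos = int(extension_length * 3)
        while i < n_genes and i < (s + 1) * per_seq:
            length = int(rng.integers(500, 3000))
            colliding = (i + 1 < min(n_genes, (s + 1) * per_seq)
                         and rng.random() < overlap_fraction)
            if colliding:
                end_a = add_gene(i, seqid, pos, length, "+")
                gap = int(rng.integers(50, max(51, extension_length - 100)))
                length_b = int(rng.integers(500, 3000))
                add_gene(i + 1, seqid, end_a + 1 + gap, length_b, "-")
                pos = end_a + 1 + gap + length_b + 3 * extension_length \
                    + int(rng.integers(0, 5000))
                i += 2
            else:
                strand = "+" if rng.random() < 0.5 else "-"
                end_a = add_gene(i, seqid, pos, length, strand)
                pos = end_a + 3 * extension_length + int(rng.integers(0, 5000))
                i += 1
        sequence_lengths[seqid] = pos + 10 * extension_length

    ann = GenomeAnnotation(records=records, sequence_lengths=sequence_lengths)
    ann.validate()
    policy = ExtensionPolicy(extension_length=extension_length,
                             overlap_scope="any-strand", on_overlap="skip")
    truth = brute_force_blocked(ann, policy)
    return ann, truth
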