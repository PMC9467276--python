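"""Shared fixtures: small simulated cohorts and toy annotation text."""

from dataclasses import replace

import numpy as np
import pytest

from balfkit.cluster import log_normalize
from balfkit.simulate import (
    PopulationSpec,
    default_balf_config,
    simulate_balf,
)

TOY_GFF3 = """\
##gff-version 3
##sequence-region chr1 1 50000
chr1\ttest\tgene\t100\t500\t.\t+\t.\tID=geneA
chr1\ttest\tmRNA\t100\t500\t.\t+\t.\tID=txA;Parent=geneA
chr1\ttest\texon\t100\t500\t.\t+\t.\tID=txA.e1;Parent=txA
"""


@pytest.fixture(scope="session")
def toy_gff3_text() -> str:
    return TOY_GFF3


def small_config(seed: int, n_cells: int = 800, n_genes: int = 2000,
                 low: int = 20, high: int = 20):
    """Default BALF composition scaled down for fast unit tests."""
    base = default_balf_config(seed)
    return replace(base, n_cells=n_cells, n_genes=n_genes,
                   qc_fail_low_genes=low, qc_fail_high_mito=high)


def two_subtype_config(seed: int, n_cells: int = 400, n_genes: int = 1500):
    """Two planted subtypes of one parent population, for sub-clustering."""
    pops = tuple(
        PopulationSpec(
            name=name, fraction=0.5,
            marker_genes=tuple(f"{name}_sig{i:02d}" for i in range(30)),
            parent_type="t_cell",
        )
        for name in ("sub_a", "sub_b")
    )
    base = default_balf_config(seed)
    return replace(base, n_cells=n_cells, n_genes=n_genes, populations=pops,
                   doublet_fraction=0.0, qc_fail_low_genes=0,
                   qc_fail_high_mito=0)


@pytest.fixture(scope="session")
def small_cohort():
    """(CountMatrix, GroundTruth) at 800 cells × 2,000 genes, seed 7."""
    return simulate_balf(small_config(7))


@pytest.fixture(scope="session")
def small_normalized(small_cohort):
    matrix, _ = small_cohort
    return log_normalize(matrix)


@pytest.fixture(scope="session")
def clean_cohort():
    """A cohort without planted QC failures or doublets (all cells usable)."""
    cfg = replace(small_config(11), qc_fail_low_genes=0, qc_fail_high_mito=0,
                  doublet_fraction=0.0)
    return simulate_balf(cfg)


@pytest.fixture(scope="session")
def clean_normalized(clean_cohort):
    matrix, _ = clean_cohort
    return log_normalize(matrix)
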