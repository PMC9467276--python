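"""Pipeline configuration: YAML parsing, defaults, validation.

An empty config file is valid and yields the full default analysis: QC at
the published thresholds (200–6,500 genes, ≤15% mito), counts-per-10k
log-normalization, 2,000 HVGs, 16 PCs at resolution 1.0 top-level with the
Mo/Ma (13 PCs/1.2), T (11 PCs/0.5) and B/plasma (8 PCs/0.7) sub-clustering
presets, and the canonical BALF marker panels.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from balfkit.errors import ArgumentError
from balfkit.annotate import DEFAULT_MARKER_PANELS
from balfkit.cluster import (
    CLUSTER_PRESETS,
    DEFAULT_K_NEIGHBORS,
    DEFAULT_N_HVG,
    DEFAULT_SNN_PRUNE,
)
from balfkit.qc import QCThresholds

__all__ = ["PipelineConfig", "validate_config", "serialize_config",
           "EXAMPLE_S_GENES", "EXAMPLE_G2M_GENES"]

# Example cell-cycle gene lists (human S / G2M symbols commonly used for
# cycle scoring; supply species-appropriate orthologs for real data).
EXAMPLE_S_GENES = [
    "MCM5", "PCNA", "TYMS", "FEN1", "MCM2", "MCM4", "RRM1", "UNG", "GINS2",
    "MCM6", "CDCA7", "DTL", "PRIM1", "UHRF1", "HELLS", "RFC2", "RPA2",
    "NASP", "RAD51AP1", "GMNN",
]
EXAMPLE_G2M_GENES = [
    "HMGB2", "CDK1", "NUSAP1", "UBE2C", "BIRC5", "TPX2", "TOP2A", "NDC80",
    "CKS2", "NUF2", "CKS1B", "MKI67", "TMPO", "CENPF", "TACC3", "SMC4",
    "CCNB2", "CKAP2", "AURKB", "BUB1",
]


@dataclass
class PipelineConfig:
    """Validated, fully-defaulted configuration for one pipeline run."""

    matrix_dir: str | None = None
    annotation_file: str | None = None
    output_dir: str = "balf_output"

    min_genes: int = 200
    max_genes: int = 6500
    max_pct_mito: float = 15.0
    mito_prefix: str = "MT-"
    mito_gene_list: list[str] = field(default_factory=list)

    scale_factor: float = 1e4
    n_hvg: int = DEFAULT_N_HVG
    n_pcs: int = 16
    resolution: float = 1.0
    k_neighbors: int = DEFAULT_K_NEIGHBORS
    snn_prune: float = DEFAULT_SNN_PRUNE
    min_subset_cells: int = 50

    marker_panels: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v)
                                 for k, v in DEFAULT_MARKER_PANELS.items()})
    s_genes: list[str] = field(default_factory=list)
    g2m_genes: list[str] = field(default_factory=list)
    assignment_margin: float = 0.05

    seed: int = 0
    run_qc: bool = True
    run_markers: bool = True
    run_subsets: bool = True
    run_cell_cycle: bool = False
    run_umap: bool = False

    def qc_thresholds(self) -> QCThresholds:
        return QCThresholds(min_genes=self.min_genes, max_genes=self.max_genes,
                            max_pct_mito=self.max_pct_mito)

    def subset_presets(self) -> dict[str, tuple[int, float]]:
        return {name: (p.n_pcs, p.resolution)
                for name, p in CLUSTER_PRESETS.items() if name != "top_level"}


def validate_config(raw_text: str | None) -> PipelineConfig:
    """Parse YAML key-value text, fill defaults, check invariants.

    Unknown keys are an error naming the key; invariant violations name the
    field. Empty input yields the full default configuration.
    """
    data = yaml.safe_load(raw_text) if raw_text else None
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ArgumentError("config must be a YAML mapping")

    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ArgumentError(f"unknown config key(s): {sorted(unknown)}")

    cfg = PipelineConfig(**data)
    cfg.qc_thresholds()  # raises on min/max genes or mito-percent violations
    if cfg.n_hvg <= 0:
        raise ArgumentError("n_hvg must be positive")
    if cfg.n_pcs < 1:
        raise ArgumentError("n_pcs must be >= 1")
    if cfg.resolution <= 0:
        raise ArgumentError("resolution must be positive")
    if cfg.k_neighbors < 2:
        raise ArgumentError("k_neighbors must be >= 2")
    if not 0 <= cfg.snn_prune < 1:
        raise ArgumentError("snn_prune must be in [0, 1)")
    if cfg.scale_factor <= 0:
        raise ArgumentError("scale_factor must be positive")
    if not 0 <= cfg.assignment_margin:
        raise ArgumentError("assignment_margin must be >= 0")
    if cfg.min_subset_cells <= cfg.k_neighbors:
        raise ArgumentError(
            "min_subset_cells must exceed k_neighbors for sub-clustering"
        )
    for ptype, genes in cfg.marker_panels.items():
        if not genes:
            raise ArgumentError(f"marker panel {ptype!r} is empty")
    return cfg


def serialize_config(config: PipelineConfig) -> str:
    """YAML text that revalidates to an identical configuration."""
    return yaml.safe_dump(asdict(config), sort_keys=True)
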