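"""Differential cell counts and the cytology vs scRNA-seq comparison.

Conventional BALF cytology distinguishes five leukocyte classes under the
microscope: macrophages, lymphocytes, neutrophils, mast cells and
eosinophils. scRNA-seq resolves finer types, which are collapsed back for
comparison: T and B/plasma cells count as lymphocytes, while
monocytes/macrophages and dendritic cells count as macrophages. The
lymphocyte/macrophage ratio is the headline summary of that comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from balfkit.errors import ArgumentError
from balfkit.annotate import CellTypeAssignment

__all__ = [
    "CYTOLOGY_CLASSES",
    "DifferentialCellCount",
    "collapse_to_cytology_classes",
    "lymphocyte_macrophage_ratio",
    "compare_dcc",
]

CYTOLOGY_CLASSES = ["lymphocytes", "macrophages", "neutrophils",
                    "mast_cells", "eosinophils"]

#: major type → cytology class
_CLASS_MAP = {
    "t_cell": "lymphocytes",
    "b_plasma": "lymphocytes",
    "mo_ma": "macrophages",
    "dc": "macrophages",
    "neutrophil": "neutrophils",
    "mast": "mast_cells",
    "eosinophil": "eosinophils",
}


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (what a printed clinical table uses)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class DifferentialCellCount:
    """Percentages over the five cytology classes for one (sample, source).

    ``percentages`` holds unrounded values; display rounding never feeds back
    into computation.
    """

    percentages: dict[str, float]
    n_cells: int
    source: str = "scrnaseq"  # cytology | scrnaseq | synthetic-truth
    sample: str = ""
    n_unassigned: int = 0

    def __post_init__(self) -> None:
        for cls in CYTOLOGY_CLASSES:
            self.percentages.setdefault(cls, 0.0)
        total = sum(self.percentages[c] for c in CYTOLOGY_CLASSES)
        # printed tables carry per-class rounding, so allow a few tenths
        if self.n_cells >= 0 and not 99.5 <= total <= 100.5:
            raise ArgumentError(
                f"class percentages sum to {total:.3f}, not 100"
            )

    def rounded(self) -> dict[str, float]:
        return {c: round_half_up(self.percentages[c])
                for c in CYTOLOGY_CLASSES}


def collapse_to_cytology_classes(assignment: CellTypeAssignment,
                                 sample: str = "",
                                 source: str = "scrnaseq"
                                 ) -> DifferentialCellCount:
    """Collapse per-cell major types into the five cytology classes.

    Unassigned cells are excluded from the denominator (their count is kept
    on the result and a warning is emitted); with zero assigned cells the
    collapse is undefined.
    """
    counts = assignment.cell_types.value_counts()
    n_unassigned = int(counts.get("unassigned", 0))
    assigned = counts.drop("unassigned", errors="ignore")
    unknown = [t for t in assigned.index if t not in _CLASS_MAP]
    if unknown:
        raise ArgumentError(f"major types without a cytology class: {unknown}")
    n_assigned = int(assigned.sum())
    if n_assigned == 0:
        raise ArgumentError("no assigned cells; cannot compute a DCC")
    if n_unassigned:
        warnings.warn(
            f"{n_unassigned} unassigned cell(s) excluded from the DCC "
            "denominator",
            stacklevel=2,
        )
    pct = {cls: 0.0 for cls in CYTOLOGY_CLASSES}
    for mtype, n in assigned.items():
        pct[_CLASS_MAP[mtype]] += 100.0 * n / n_assigned
    return DifferentialCellCount(percentages=pct, n_cells=n_assigned,
                                 source=source, sample=sample,
                                 n_unassigned=n_unassigned)


def lymphocyte_macrophage_ratio(dcc: DifferentialCellCount) -> float:
    """Lymphocyte % divided by macrophage %, half-up rounded to 1 decimal."""
    macro = dcc.percentages["macrophages"]
    if macro == 0:
        raise ArgumentError(
            "macrophage percentage is 0; lymphocyte/macrophage ratio undefined"
        )
    return round_half_up(dcc.percentages["lymphocytes"] / macro)


def compare_dcc(entries: list[DifferentialCellCount]) -> pd.DataFrame:
    """Wide comparison table: one column per (sample, source), rows = classes + ratio."""
    if not entries:
        raise ArgumentError("need at least one DCC entry")
    keys = [(d.sample, d.source) for d in entries]
    if len(set(keys)) != len(keys):
        raise ArgumentError(f"duplicate (sample, source) keys in {keys}")
    data = {}
    for d in entries:
        col = {cls: round_half_up(d.percentages[cls])
               for cls in CYTOLOGY_CLASSES}
        col["lymphocytes_macrophages"] = lymphocyte_macrophage_ratio(d)
        data[(d.sample, d.source)] = col
    table = pd.DataFrame(data)
    table.columns = pd.MultiIndex.from_tuples(table.columns,
                                              names=["sample", "source"])
    return table.loc[CYTOLOGY_CLASSES + ["lymphocytes_macrophages"]]


def dcc_from_percentages(percentages: dict[str, float], sample: str,
                         source: str, n_cells: int = 0
                         ) -> DifferentialCellCount:
    """Build a DCC from externally counted percentages (e.g. manual cytology)."""
    return DifferentialCellCount(percentages=dict(percentages),
                                 n_cells=n_cells, source=source, sample=sample)
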