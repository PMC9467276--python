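"""Genome-annotation model and 3'-UTR extension.

Droplet-based 3' scRNA-seq assays place most reads at the 3' end of
transcripts. When a reference annotation under-calls 3'-UTRs (common in
non-model species), many reads fall just downstream of the annotated
transcript end and are lost from the count matrix. The remedy implemented
here extends every transcript's 3' end by a fixed length (default 2 kb),
unless the extension would run into a neighboring gene, in which case the
transcript is either left alone (``skip``) or extended up to 1 bp short of
the neighbor (``truncate``). The parent gene span and the 3'-most exon are
moved along with the transcript so that exon-level read counting benefits.

Coordinates follow the GFF3 convention throughout: 1-based, inclusive.
"""

from __future__ import annotations

import io as _io
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterator

import pandas as pd
from intervaltree import IntervalTree

from balfkit.errors import ArgumentError, ParseError, StructureError

__all__ = [
    "AnnotationRecord",
    "GenomeAnnotation",
    "ExtensionPolicy",
    "ExtensionReport",
    "parse_annotation",
    "write_annotation",
    "three_prime_extension_interval",
    "extend_three_prime",
]

# normalized feature kinds
GENE = "gene"
TRANSCRIPT = "transcript"
EXON = "exon"
OTHER = "other"

_TRANSCRIPT_TYPES = {
    "mRNA", "transcript", "lnc_RNA", "ncRNA", "snRNA", "snoRNA", "rRNA",
    "tRNA", "miRNA", "pseudogenic_transcript", "V_gene_segment",
    "C_gene_segment", "guide_RNA", "antisense_RNA",
}
_KIND_RANK = {GENE: 0, TRANSCRIPT: 1, EXON: 2, OTHER: 3}


def _normalize_kind(feature_type: str) -> str:
    if feature_type == "gene" or feature_type.endswith("_gene"):
        return GENE
    if feature_type in _TRANSCRIPT_TYPES:
        return TRANSCRIPT
    if feature_type == "exon":
        return EXON
    return OTHER


@dataclass
class AnnotationRecord:
    """One GFF3/GTF feature line, with normalized hierarchy metadata."""

    seqid: str
    feature_type: str  # as in the file (e.g. "mRNA")
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # "+", "-" or "."
    id: str
    parent: str | None = None
    source: str = "."
    score: str = "."
    phase: str = "."
    attributes: str = ""  # raw 9th column, preserved for round-trip

    @property
    def feature_kind(self) -> str:
        return _normalize_kind(self.feature_type)

    def sort_key(self) -> tuple:
        return (self.seqid, self.start, -self.end,
                _KIND_RANK[self.feature_kind], self.id)


@dataclass
class GenomeAnnotation:
    """Hierarchical gene/transcript/exon model with 1-based coordinates."""

    records: list[AnnotationRecord] = field(default_factory=list)
    sequence_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index()

    def _index(self) -> None:
        self.records.sort(key=AnnotationRecord.sort_key)
        self.by_id: dict[str, AnnotationRecord] = {}
        self.children: dict[str, list[AnnotationRecord]] = {}
        for rec in self.records:
            if rec.id in self.by_id:
                raise StructureError(f"duplicate feature ID {rec.id!r}")
            self.by_id[rec.id] = rec
        for rec in self.records:
            if rec.parent is not None:
                if rec.parent not in self.by_id:
                    raise StructureError(
                        f"feature {rec.id!r} has dangling Parent {rec.parent!r}"
                    )
                self.children.setdefault(rec.parent, []).append(rec)

    def validate(self) -> None:
        """Check coordinate and containment invariants; raise StructureError."""
        for rec in self.records:
            if rec.start < 1 or rec.start > rec.end:
                raise StructureError(
                    f"feature {rec.id!r} has invalid interval "
                    f"[{rec.start}, {rec.end}]"
                )
            if rec.parent is not None:
                par = self.by_id[rec.parent]
                if rec.seqid != par.seqid:
                    raise StructureError(
                        f"feature {rec.id!r} on {rec.seqid} but parent "
                        f"{par.id!r} on {par.seqid}"
                    )
                if rec.start < par.start or rec.end > par.end:
                    raise StructureError(
                        f"feature {rec.id!r} [{rec.start}, {rec.end}] not "
                        f"contained in parent {par.id!r} "
                        f"[{par.start}, {par.end}]"
                    )
        for seqid, length in self.sequence_lengths.items():
            for rec in self.records:
                if rec.seqid == seqid and rec.end > length:
                    raise StructureError(
                        f"feature {rec.id!r} ends at {rec.end}, beyond "
                        f"sequence {seqid} length {length}"
                    )

    def genes(self) -> Iterator[AnnotationRecord]:
        return (r for r in self.records if r.feature_kind == GENE)

    def transcripts(self) -> Iterator[AnnotationRecord]:
        return (r for r in self.records if r.feature_kind == TRANSCRIPT)

    def exons_of(self, transcript_id: str) -> list[AnnotationRecord]:
        return [r for r in self.children.get(transcript_id, [])
                if r.feature_kind == EXON]

    def copy(self) -> "GenomeAnnotation":
        return GenomeAnnotation(
            records=[replace(r) for r in self.records],
            sequence_lengths=dict(self.sequence_lengths),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeAnnotation):
            return NotImplemented
        mine = [(r.seqid, r.feature_type, r.start, r.end, r.strand, r.id,
                 r.parent) for r in self.records]
        theirs = [(r.seqid, r.feature_type, r.start, r.end, r.strand, r.id,
                   r.parent) for r in other.records]
        return mine == theirs and self.sequence_lengths == other.sequence_lengths


@dataclass(frozen=True)
class ExtensionPolicy:
    """How to extend 3' ends and what counts as a blocking overlap.

    ``overlap_scope="any-strand"`` is the conservative default: a gene on
    either strand blocks the extension. A 3' assay counts strand-specifically,
    so ``"same-strand"`` is offered for users who accept antisense overlap.
    """

    extension_length: int = 2000
    overlap_scope: str = "any-strand"  # or "same-strand"
    on_overlap: str = "skip"  # or "truncate"
    clamp_low: bool = True
    clamp_high: bool = True

    def __post_init__(self) -> None:
        if self.extension_length < 0:
            raise ArgumentError("extension_length must be >= 0")
        if self.overlap_scope not in ("any-strand", "same-strand"):
            raise ArgumentError(f"unknown overlap_scope {self.overlap_scope!r}")
        if self.on_overlap not in ("skip", "truncate"):
            raise ArgumentError(f"unknown on_overlap {self.on_overlap!r}")


#: per-transcript outcome table; columns fixed for the TSV report
REPORT_COLUMNS = ["transcript_id", "gene_id", "seqid", "strand", "status",
                  "old_end3", "new_end3", "blocking_gene_id"]

ExtensionReport = pd.DataFrame


# ---------------------------------------------------------------------------
# parsing / writing
# ---------------------------------------------------------------------------

_GFF3_ATTR = re.compile(r"([^=;\s][^=;]*)=([^;]*)")


def _parse_gff3_attributes(attr: str) -> dict[str, str]:
    return {m.group(1).strip(): m.group(2).strip()
            for m in _GFF3_ATTR.finditer(attr)}


_GTF_ATTR = re.compile(r'(\S+)\s+"([^"]*)"')


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    return {m.group(1): m.group(2) for m in _GTF_ATTR.finditer(attr)}


def parse_annotation(source, dialect: str = "gff3") -> GenomeAnnotation:
    """Parse a GFF3 (or GTF, with ``dialect="gtf"``) stream or path.

    The resulting model is canonically ordered, so shuffling the lines of the
    input does not change it. Malformed lines raise :class:`ParseError` with
    the line number; a Parent that never resolves raises
    :class:`StructureError` naming the orphan.
    """
    if dialect not in ("gff3", "gtf"):
        raise ArgumentError(f"unknown dialect {dialect!r}")
    if isinstance(source, Path):
        handle: IO[str] = open(source, "rt")
        close = True
    elif isinstance(source, str):
        if "\n" in source or "\t" in source:  # literal text, not a path
            handle, close = _io.StringIO(source), False
        else:
            handle, close = open(source, "rt"), True
    else:
        handle, close = source, False

    records: list[AnnotationRecord] = []
    sequence_lengths: dict[str, int] = {}
    anon = 0
    try:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    try:
                        sequence_lengths[parts[1]] = int(parts[3])
                    except ValueError:
                        raise ParseError("bad ##sequence-region pragma", lineno)
                continue
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(
                    f"expected 9 tab-separated columns, got {len(cols)}", lineno
                )
            seqid, src, ftype, start_s, end_s, score, strand, phase, attr = cols
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(
                    f"non-integer coordinates {start_s!r}/{end_s!r}", lineno
                )
            if start < 1 or start > end:
                raise ParseError(f"invalid interval [{start}, {end}]", lineno)
            if strand not in ("+", "-", "."):
                raise ParseError(f"invalid strand {strand!r}", lineno)
            if dialect == "gff3":
                attrs = _parse_gff3_attributes(attr)
                fid = attrs.get("ID")
                parent = attrs.get("Parent")
            else:
                attrs = _parse_gtf_attributes(attr)
                kind = _normalize_kind(ftype)
                if kind == GENE:
                    fid, parent = attrs.get("gene_id"), None
                elif kind == TRANSCRIPT:
                    fid = attrs.get("transcript_id")
                    parent = attrs.get("gene_id")
                else:
                    fid = None
                    parent = attrs.get("transcript_id") or attrs.get("gene_id")
            if fid is None:
                anon += 1
                fid = f"_anon{anon}"
            records.append(AnnotationRecord(
                seqid=seqid, feature_type=ftype, start=start, end=end,
                strand=strand, id=fid, parent=parent, source=src,
                score=score, phase=phase, attributes=attr,
            ))
    finally:
        if close:
            handle.close()

    ann = GenomeAnnotation(records=records, sequence_lengths=sequence_lengths)
    ann.validate()
    return ann


def write_annotation(annotation: GenomeAnnotation, stream=None) -> str:
    """Serialize to GFF3 text; returns the text, also writing to ``stream``.

    Coordinates are written as plain integers (never scientific notation);
    ``parse_annotation(write_annotation(a))`` reproduces ``a``.
    """
    out = _io.StringIO()
    out.write("##gff-version 3\n")
    for seqid in sorted(annotation.sequence_lengths):
        out.write(f"##sequence-region {seqid} 1 "
                  f"{annotation.sequence_lengths[seqid]:d}\n")
    for rec in annotation.records:
        attrs = rec.attributes
        # keep ID/Parent consistent with the model even if attrs were edited
        if attrs:
            parsed = _parse_gff3_attributes(attrs)
        else:
            parsed = {}
        if not rec.id.startswith("_anon"):
            parsed["ID"] = rec.id
        if rec.parent is not None:
            parsed["Parent"] = rec.parent
        attr_col = ";".join(f"{k}={v}" for k, v in parsed.items()) or "."
        out.write("\t".join([
            rec.seqid, rec.source, rec.feature_type,
            f"{rec.start:d}", f"{rec.end:d}",
            rec.score, rec.strand, rec.phase, attr_col,
        ]) + "\n")
    text = out.getvalue()
    if stream is not None:
        if isinstance(stream, (str, Path)):
            Path(stream).write_text(text)
        else:
            stream.write(text)
    return text


# ---------------------------------------------------------------------------
# extension arithmetic
# ---------------------------------------------------------------------------

def three_prime_extension_interval(
    transcript: AnnotationRecord,
    length: int,
    sequence_length: int | None = None,
) -> tuple[int, int] | None:
    """Genomic interval a 3' extension of ``length`` bp would occupy.

    ``+`` strand: ``[end+1, end+length]``; ``-`` strand:
    ``[start-length, start-1]``. The interval is clamped to
    ``[1, sequence_length]``; ``None`` means there is no room at all
    (including ``length == 0``).
    """
    if length < 0:
        raise ArgumentError("extension length must be >= 0")
    if transcript.strand not in ("+", "-"):
        raise ArgumentError(
            f"transcript {transcript.id!r} has no usable strand "
            f"({transcript.strand!r})"
        )
    if length == 0:
        return None
    if transcript.strand == "+":
        lo, hi = transcript.end + 1, transcript.end + length
    else:
        lo, hi = transcript.start - length, transcript.start - 1
    lo = max(lo, 1)
    if sequence_length is not None:
        hi = min(hi, sequence_length)
    if lo > hi:
        return None
    return (lo, hi)


def _gene_trees(
    annotation: GenomeAnnotation, scope: str
) -> dict[tuple, IntervalTree]:
    """Interval trees over gene spans, keyed by seqid (and strand if scoped)."""
    trees: dict[tuple, IntervalTree] = {}
    for g in annotation.genes():
        if scope == "same-strand":
            key = (g.seqid, g.strand)
        else:
            key = (g.seqid,)
        trees.setdefault(key, IntervalTree()).addi(g.start, g.end + 1, g.id)
    return trees


def extend_three_prime(
    annotation: GenomeAnnotation,
    policy: ExtensionPolicy | None = None,
) -> tuple[GenomeAnnotation, ExtensionReport]:
    """Extend every transcript's 3' end per ``policy``; return new model + report.

    A transcript's own parent gene never blocks it (otherwise no multi-isoform
    gene could extend). On a blocking overlap the transcript is skipped
    (default) or truncated to 1 bp short of the nearest blocker. The
    transcript record, its 3'-most exon and the parent gene span all move
    together so exon-level counting sees the extension. Deterministic;
    ``extension_length == 0`` is the identity.
    """
    if policy is None:
        policy = ExtensionPolicy()
    out = annotation.copy()
    trees = _gene_trees(out, policy.overlap_scope)
    rows: list[dict] = []

    for tx in list(out.transcripts()):
        strand = tx.strand
        old_end3 = tx.end if strand == "+" else tx.start
        gene_id = tx.parent
        seqlen = out.sequence_lengths.get(tx.seqid) if policy.clamp_high else None

        status = "unchanged"
        new_end3 = old_end3
        blocking: str | None = None

        interval = None
        if policy.extension_length > 0 and strand in ("+", "-"):
            interval = three_prime_extension_interval(
                tx, policy.extension_length, seqlen
            )

        if interval is not None:
            lo, hi = interval
            full = policy.extension_length
            achieved = (hi - old_end3) if strand == "+" else (old_end3 - lo)
            clamped = achieved < full

            key = (tx.seqid, strand) if policy.overlap_scope == "same-strand" \
                else (tx.seqid,)
            hits = trees.get(key, IntervalTree()).overlap(lo, hi + 1)
            blockers = [(iv.begin, iv.end - 1, iv.data) for iv in hits
                        if iv.data != gene_id]

            if blockers:
                if policy.on_overlap == "skip":
                    status, blocking = "blocked_overlap", \
                        min(blockers, key=lambda b: (abs(b[0] - old_end3)))[2]
                    new_end3 = old_end3
                else:  # truncate to 1 bp short of the nearest blocker
                    if strand == "+":
                        nearest = min(blockers, key=lambda b: b[0])
                        target = nearest[0] - 1
                        blocking = nearest[2]
                        if target > old_end3:
                            new_end3, status = min(target, hi), "truncated"
                        else:
                            new_end3, status = old_end3, "blocked_overlap"
                    else:
                        nearest = max(blockers, key=lambda b: b[1])
                        target = nearest[1] + 1
                        blocking = nearest[2]
                        if target < old_end3:
                            new_end3, status = max(target, lo), "truncated"
                        else:
                            new_end3, status = old_end3, "blocked_overlap"
            else:
                new_end3 = hi if strand == "+" else lo
                status = "clamped" if clamped else "extended"
        elif policy.extension_length > 0 and strand in ("+", "-"):
            # no room at all (e.g. - strand transcript starting at 1)
            status = "clamped"

        if new_end3 != old_end3:
            _apply_move(out, tx, new_end3)
        rows.append({
            "transcript_id": tx.id,
            "gene_id": gene_id,
            "seqid": tx.seqid,
            "strand": strand,
            "status": status,
            "old_end3": old_end3,
            "new_end3": new_end3,
            "blocking_gene_id": blocking,
        })

    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    out._index()
    out.validate()
    return out, report


def _apply_move(ann: GenomeAnnotation, tx: AnnotationRecord, new_end3: int) -> None:
    """Move transcript 3' boundary to ``new_end3``; drag 3'-most exon and gene."""
    exons = ann.exons_of(tx.id)
    if tx.strand == "+":
        if exons:
            last = max(exons, key=lambda e: e.end)
            last.end = max(last.end, new_end3)
        tx.end = new_end3
        if tx.parent is not None:
            gene = ann.by_id[tx.parent]
            gene.end = max(gene.end, new_end3)
    else:
        if exons:
            first = min(exons, key=lambda e: e.start)
            first.start = min(first.start, new_end3)
        tx.start = new_end3
        if tx.parent is not None:
            gene = ann.by_id[tx.parent]
            gene.start = min(gene.start, new_end3)


def write_report(report: ExtensionReport, path) -> None:
    """Write the per-transcript extension report as TSV."""
    report.to_csv(path, sep="\t", index=False)
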