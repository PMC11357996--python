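"""Alignment ingestion, a small transcript-level aligner, and coordinate projection.

Genome-scale splice-aware alignment is the job of an external aligner
(e.g. minimap2 in splice mode); this module ingests its SAM output.  For
transcript-level references (no introns) a built-in semi-global aligner
(:func:`toy_align`, edlib-backed) produces equivalent records so that the rest
of the pipeline can be exercised without any external tool.  Reference
positions are 1-based inclusive (SAM/VCF convention); read offsets 0-based.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import edlib

logger = logging.getLogger(__name__)

Cigar = tuple[tuple[str, int], ...]

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

#: CIGAR ops that consume the read / the reference
_CONSUMES_READ = frozenset("MIS=X")
_CONSUMES_REF = frozenset("MDN=X")


@dataclass(frozen=True)
class AlignmentRecord:
    """One read-to-reference alignment (primary, mapped)."""

    read_id: str
    contig: str
    ref_start: int  # 1-based inclusive
    cigar: Cigar
    strand: str = "+"
    mapq: int = 60
    gene: str | None = None

    @property
    def read_length(self) -> int:
        return sum(n for op, n in self.cigar if op in _CONSUMES_READ)

    @property
    def ref_span(self) -> int:
        return sum(n for op, n in self.cigar if op in _CONSUMES_REF)

    @property
    def ref_end(self) -> int:
        """Last reference position covered, 1-based inclusive."""
        return self.ref_start + self.ref_span - 1


@dataclass(frozen=True)
class SiteProjection:
    """Projection of one reference position through an alignment."""

    status: str  # "aligned" | "deleted" | "unaligned"
    read_offset: int | None = None  # 0-based, set iff aligned
    observed_base: str | None = None


def parse_cigar(cigar: str) -> Cigar:
    ops = _CIGAR_RE.findall(cigar)
    if not ops or "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise ValueError(f"malformed CIGAR string: {cigar!r}")
    # '='/'X' are match/mismatch refinements of M; collapse for uniformity
    merged: list[tuple[str, int]] = []
    for n, op in ops:
        op = "M" if op in "=X" else op
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + int(n))
        else:
            merged.append((op, int(n)))
    return tuple(merged)


def cigar_string(cigar: Cigar) -> str:
    return "".join(f"{n}{op}" for op, n in cigar)


def parse_sam(path) -> list[AlignmentRecord]:
    """Load primary mapped alignments from a SAM file.

    Unmapped, secondary and supplementary records are dropped (the behaviour
    of a ``--sam-hit-only`` aligner run).  Records whose CIGAR is inconsistent
    with the stored sequence are logged per read and skipped; parsing of the
    remaining file continues.
    """
    import pysam

    lines = Path(path).read_text().splitlines()
    header = pysam.AlignmentHeader.from_text(
        "".join(line + "\n" for line in lines if line.startswith("@")) or "@HD\tVN:1.6\n"
    )
    records: list[AlignmentRecord] = []
    for lineno, line in enumerate(lines, 1):
        if not line or line.startswith("@"):
            continue
        # per-record parsing isolates malformed records: log and continue
        try:
            rec = pysam.AlignedSegment.fromstring(line, header)
        except ValueError as exc:
            logger.warning("skipping SAM line %d (%s): %s", lineno, line.split("\t")[0], exc)
            continue
        if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
            continue
        try:
            cigar = parse_cigar(rec.cigarstring or "")
            record = AlignmentRecord(
                read_id=rec.query_name,
                contig=rec.reference_name,
                ref_start=rec.reference_start + 1,
                cigar=cigar,
                strand="-" if rec.is_reverse else "+",
                mapq=rec.mapping_quality,
                gene=dict(rec.tags).get("GE"),
            )
            seq = rec.query_sequence
            if seq is not None and record.read_length != len(seq):
                raise ValueError(
                    f"CIGAR consumes {record.read_length} read bases, "
                    f"sequence has {len(seq)}"
                )
        except ValueError as exc:
            logger.warning("skipping SAM record %s: %s", rec.query_name, exc)
            continue
        records.append(record)
    return records


def read_sam_sequences(path) -> dict[str, str]:
    """Stored query sequences of primary mapped SAM records (first occurrence wins)."""
    import pysam

    lines = Path(path).read_text().splitlines()
    header = pysam.AlignmentHeader.from_text(
        "".join(line + "\n" for line in lines if line.startswith("@")) or "@HD\tVN:1.6\n"
    )
    out: dict[str, str] = {}
    for line in lines:
        if not line or line.startswith("@"):
            continue
        try:
            rec = pysam.AlignedSegment.fromstring(line, header)
        except ValueError:
            continue
        if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
            continue
        if rec.query_sequence:
            out.setdefault(rec.query_name, rec.query_sequence)
    return out


def toy_align(
    read: str,
    reference: str,
    *,
    contig: str = "ref",
    read_id: str = "read",
    gene: str | None = None,
    max_edit_frac: float = 0.4,
) -> AlignmentRecord | None:
    """Semi-global alignment of a read inside an ungapped transcript reference.

    Free end gaps on the reference, unit edit costs (edlib infix mode); the
    CIGAR reports M for match and mismatch alike.  Returns ``None`` when the
    best edit distance exceeds ``max_edit_frac`` x read length (unaligned).
    """
    if not read:
        return None
    k = int(max_edit_frac * len(read))
    hit = edlib.align(read, reference, mode="HW", task="path", k=k)
    if hit["editDistance"] < 0:
        return None
    start = min(loc[0] for loc in hit["locations"])
    return AlignmentRecord(
        read_id=read_id,
        contig=contig,
        ref_start=start + 1,
        cigar=parse_cigar(hit["cigar"]),
        gene=gene,
    )


def toy_align_best(
    read: str,
    reference: "dict[str, str]",
    *,
    read_id: str = "read",
    max_edit_frac: float = 0.4,
) -> AlignmentRecord | None:
    """Align against every contig of a transcript reference; keep the best hit.

    Contigs are ranked by edit distance; ties resolve to the lexicographically
    smallest contig name (deterministic).
    """
    best: tuple[int, str, AlignmentRecord] | None = None
    k = int(max_edit_frac * len(read)) if read else 0
    for contig in sorted(reference):
        hit = edlib.align(read, reference[contig], mode="HW", task="distance", k=k)
        if hit["editDistance"] < 0:
            continue
        if best is None or hit["editDistance"] < best[0]:
            rec = toy_align(
                read, reference[contig], contig=contig, read_id=read_id,
                gene=contig, max_edit_frac=max_edit_frac,
            )
            best = (hit["editDistance"], contig, rec)
    return best[2] if best else None


def project_site(aln: AlignmentRecord, contig: str, pos: int) -> SiteProjection:
    """Project reference position ``pos`` (1-based) onto the read.

    M consumes both coordinates; I and S consume the read only; D and N
    consume the reference only.  A position inside a D run is ``deleted``;
    inside an N run (spliced-out) or outside the reference span it is
    ``unaligned`` — absence of coverage, not a deletion allele.
    """
    if contig != aln.contig:
        return SiteProjection("unaligned")
    ref = aln.ref_start
    off = 0
    for op, n in aln.cigar:
        if op == "M":
            if ref <= pos < ref + n:
                return SiteProjection("aligned", read_offset=off + (pos - ref))
            ref += n
            off += n
        elif op in ("I", "S"):
            off += n
        elif op == "D":
            if ref <= pos < ref + n:
                return SiteProjection("deleted")
            ref += n
        elif op == "N":
            if ref <= pos < ref + n:
                return SiteProjection("unaligned")
            ref += n
        # H consumes neither
    return SiteProjection("unaligned")


def aligned_columns(
    aln: AlignmentRecord, sequence: str
) -> tuple[dict[int, str], dict[int, str]]:
    """Reference-anchored column layout of one aligned read.

    Returns ``(columns, insertions)`` where ``columns`` maps each covered
    1-based reference position to the observed base ('-' inside deletions) and
    ``insertions`` maps a reference position to the read bases inserted
    immediately *before* it.  N runs leave their positions uncovered.
    """
    columns: dict[int, str] = {}
    insertions: dict[int, str] = {}
    ref = aln.ref_start
    off = 0
    for op, n in aln.cigar:
        if op == "M":
            for k in range(n):
                columns[ref + k] = sequence[off + k]
            ref += n
            off += n
        elif op == "I":
            insertions[ref] = insertions.get(ref, "") + sequence[off : off + n]
            off += n
        elif op == "S":
            off += n
        elif op == "D":
            for k in range(n):
                columns[ref + k] = "-"
            ref += n
        elif op == "N":
            ref += n
    return columns, insertions


def write_alignments_tsv(records: Iterable[AlignmentRecord], path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["read_id", "contig", "ref_start", "cigar", "strand", "mapq", "gene"])
        for r in records:
            writer.writerow(
                [r.read_id, r.contig, r.ref_start, cigar_string(r.cigar),
                 r.strand, r.mapq, r.gene or ""]
            )
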