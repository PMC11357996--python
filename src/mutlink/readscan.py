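"""Scan long reads for the adapter and the poly-(A/T) tract and orient them.

Each raw Nanopore read of a 10x 3' library carries, in one orientation or the
other, the Read-1 adapter followed by the 16-nt cell barcode, the 12-nt UMI, a
homopolymer tract and the cDNA body.  A read is usable for demultiplexing only
if both the adapter and the homopolymer tract can be located; everything else
is gated out here with an explicit drop reason.  Reads are reported in *sense*
orientation, i.e. rotated so that the adapter sits at the 5' end.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from typing import Iterable, Iterator

import edlib

from .seq import revcomp
from .simulate import ReadStructure

#: extra bases kept after the barcode+UMI span for indel-tolerant matching
BARCODE_WINDOW_SLACK = 4


@dataclass(frozen=True)
class LongRead:
    """A raw long read: identifier, sequence, optional Phred+33 quality."""

    read_id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id!r} has an empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )


@dataclass(frozen=True)
class ScanResult:
    """Outcome of scanning one read.

    ``adapter_end`` and ``polya_start`` are 0-based offsets into the oriented
    read; ``barcode_window`` is the slice between them (capped at
    barcode_len + umi_len + slack).  ``cdna_start`` marks the first base after
    the homopolymer tract, i.e. the start of the cDNA body.
    """

    read_id: str
    kept: bool
    orientation: str | None = None  # "sense" | "antisense"
    adapter_end: int | None = None
    polya_start: int | None = None
    cdna_start: int | None = None
    barcode_window: str | None = None
    oriented_sequence: str | None = None
    oriented_quality: str | None = None
    reason: str | None = None


def _locate_adapter(
    sequence: str, adapter: str, search_window: int, max_edit: int
) -> tuple[int, int, int] | None:
    """Best semi-global adapter hit within the first ``search_window`` bases.

    Returns (edit_distance, start, end_exclusive) or None when the best hit
    exceeds ``max_edit``.  Ties on distance resolve to the smallest start.
    """
    target = sequence[:search_window]
    hit = edlib.align(adapter, target, mode="HW", task="locations", k=max_edit)
    if hit["editDistance"] < 0:
        return None
    start, end = min(hit["locations"])  # ties resolve to the smallest start
    return hit["editDistance"], start, end + 1


def scan_read(
    read: LongRead,
    structure: ReadStructure | None = None,
    *,
    adapter_max_edit: int = 3,
    polya_min_len: int = 10,
    search_window: int = 200,
) -> ScanResult:
    """Parse one read for the adapter and poly-(A/T) tract and orient it.

    The adapter is searched in both the read and its reverse complement; the
    orientation with the better (smaller) edit distance wins, sense preferred
    on ties.  Downstream of the adapter a run of >= ``polya_min_len`` A's is
    required (in the oriented read the poly-(A/T) tract reads as A's).  Reads
    lacking either feature are returned with ``kept=False`` and a reason.
    """
    structure = structure or ReadStructure()
    candidates = []
    rc = revcomp(read.sequence)
    for oriented, orientation in ((read.sequence, "sense"), (rc, "antisense")):
        hit = _locate_adapter(
            oriented, structure.adapter_r1, search_window, adapter_max_edit
        )
        if hit is not None:
            candidates.append((hit[0], 0 if orientation == "sense" else 1, hit, oriented, orientation))
    if not candidates:
        return ScanResult(read.read_id, kept=False, reason="no_adapter")
    candidates.sort(key=lambda c: (c[0], c[2][1], c[1]))
    _, _, (_, _, adapter_end), oriented, orientation = candidates[0]

    # strictly downstream of the adapter (kept implies adapter_end < polya_start)
    match = re.compile("A{%d,}" % polya_min_len).search(oriented, adapter_end + 1)
    if match is None:
        return ScanResult(read.read_id, kept=False, reason="no_polyA")
    polya_start, cdna_start = match.start(), match.end()

    window_cap = structure.barcode_len + structure.umi_len + BARCODE_WINDOW_SLACK
    window = oriented[adapter_end : min(polya_start, adapter_end + window_cap)]
    quality = read.quality
    if quality is not None and orientation == "antisense":
        quality = quality[::-1]
    return ScanResult(
        read_id=read.read_id,
        kept=True,
        orientation=orientation,
        adapter_end=adapter_end,
        polya_start=polya_start,
        cdna_start=cdna_start,
        barcode_window=window,
        oriented_sequence=oriented,
        oriented_quality=quality,
    )


def scan_reads(
    reads: Iterable[LongRead],
    structure: ReadStructure | None = None,
    **params,
) -> Iterator[ScanResult]:
    for read in reads:
        yield scan_read(read, structure, **params)


def read_fastq(path) -> Iterator[LongRead]:
    """Iterate a FASTQ file as LongRead records (pysam-backed)."""
    import pysam

    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            yield LongRead(entry.name, entry.sequence, entry.quality)


def write_scan_tsv(results: Iterable[ScanResult], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["read_id", "kept", "orientation", "adapter_end", "polya_start",
             "cdna_start", "barcode_window", "reason"]
        )
        for r in results:
            writer.writerow(
                [r.read_id, int(r.kept), r.orientation or "", r.adapter_end,
                 r.polya_start, r.cdna_start, r.barcode_window or "", r.reason or ""]
            )


def write_kept_fastq(results: Iterable[ScanResult], path) -> None:
    """Write kept reads, oriented adapter-first, as FASTQ."""
    with open(path, "w") as fh:
        for r in results:
            if not r.kept:
                continue
            qual = r.oriented_quality or "I" * len(r.oriented_sequence)
            fh.write(f"@{r.read_id}\n{r.oriented_sequence}\n+\n{qual}\n")
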