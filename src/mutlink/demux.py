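"""Cell-barcode and UMI assignment against a short-read-derived whitelist.

Every kept, oriented read is matched against the whitelist of cell barcodes
observed in the short-read library.  Matching is semi-global (free end gaps
over a small slack window after the adapter) with an allowed edit distance of
1 by default; the UMI is the stretch of bases immediately following the
matched barcode span and is taken verbatim — downstream grouping uses UMI
identity, so no UMI error correction is attempted.  Reads whose minimal-
distance barcode is not unique are flagged ambiguous and excluded downstream.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import edlib

from .readscan import BARCODE_WINDOW_SLACK, ScanResult


@dataclass(frozen=True)
class Whitelist:
    """Deduplicated set of fixed-length cell barcodes."""

    barcodes: frozenset[str]
    length: int

    def __post_init__(self) -> None:
        if not self.barcodes:
            raise ValueError("whitelist is empty")
        lengths = {len(b) for b in self.barcodes}
        if lengths != {self.length}:
            raise ValueError(f"mixed barcode lengths in whitelist: {sorted(lengths)}")

    def __len__(self) -> int:
        return len(self.barcodes)

    def __contains__(self, barcode: str) -> bool:
        return barcode in self.barcodes


def build_whitelist(source) -> Whitelist:
    """Build a Whitelist from a TSV path (one barcode per line) or an iterable."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            entries = [line.strip() for line in fh if line.strip()]
    else:
        entries = [str(b).strip() for b in source]
    if not entries:
        raise ValueError("whitelist source is empty")
    lengths = {len(b) for b in entries}
    if len(lengths) != 1:
        raise ValueError(f"mixed barcode lengths in whitelist: {sorted(lengths)}")
    return Whitelist(frozenset(entries), lengths.pop())


@dataclass(frozen=True)
class BarcodeAssignment:
    """The (cell barcode, UMI) tag attached to one read."""

    read_id: str
    status: str  # "assigned" | "ambiguous" | "unmatched"
    cell_barcode: str | None = None
    umi: str | None = None
    bc_edit_distance: int | None = None


def match_umi(
    raw_umi: str, known_umis, max_edit: int = 1
) -> str | None:
    """Match an extracted UMI against the cell's known (short-read) UMIs.

    Exact hits win; otherwise the unique known UMI within ``max_edit``
    (global Levenshtein) is returned as the corrected UMI.  ``None`` means no
    unique match — the read cannot be attributed to a known molecule.
    """
    if raw_umi in known_umis:
        return raw_umi
    hits = []
    for umi in known_umis:
        d = edlib.align(raw_umi, umi, mode="NW", task="distance", k=max_edit)["editDistance"]
        if d >= 0:
            hits.append(umi)
            if len(hits) > 1:
                return None
    return hits[0] if len(hits) == 1 else None


def assign_barcode(
    scan: ScanResult,
    wl: Whitelist,
    max_edit: int = 1,
    *,
    umi_len: int = 12,
    umi_whitelist: "dict[str, frozenset[str]] | None" = None,
) -> BarcodeAssignment:
    """Assign the unique minimal-distance whitelist barcode to a kept read.

    The barcode is searched semi-globally in the prefix region of the slack
    window after the adapter (window length ``barcode_len + max_edit`` so one
    indel before or inside the barcode is tolerated).  The UMI is the next
    ``umi_len`` bases after the matched barcode span; when a per-cell UMI
    whitelist (from the short-read library) is supplied, the UMI is matched
    against the assigned cell's known UMIs at edit distance <= ``max_edit``
    and reads without a unique UMI match are reported unmatched.
    """
    if not scan.kept:
        raise ValueError(f"read {scan.read_id!r} was not kept by the scanner")
    region = scan.oriented_sequence[
        scan.adapter_end : scan.adapter_end + wl.length + umi_len + BARCODE_WINDOW_SLACK
    ]
    target = region[: wl.length + max_edit]

    # exact-substring shortcut: a distance-0 hit is an exact occurrence of a
    # whitelist entry inside the target; consistent with the full search.
    exact = {
        target[off : off + wl.length]
        for off in range(len(target) - wl.length + 1)
    } & wl.barcodes
    if exact:
        if len(exact) > 1:
            return BarcodeAssignment(scan.read_id, "ambiguous", bc_edit_distance=0)
        barcode = next(iter(exact))
        end = target.index(barcode) + wl.length  # smallest start on ties
        return _finalize(
            scan.read_id, barcode, 0, region[end : end + umi_len], umi_whitelist, max_edit
        )

    best_distance: int | None = None
    best: list[str] = []
    for barcode in wl.barcodes:
        hit = edlib.align(barcode, target, mode="HW", task="distance", k=max_edit)
        d = hit["editDistance"]
        if d < 0:
            continue
        if best_distance is None or d < best_distance:
            best_distance, best = d, [barcode]
        elif d == best_distance:
            best.append(barcode)
    if best_distance is None:
        return BarcodeAssignment(scan.read_id, "unmatched")
    if len(best) > 1:
        return BarcodeAssignment(scan.read_id, "ambiguous", bc_edit_distance=best_distance)
    barcode = best[0]
    loc = edlib.align(barcode, target, mode="HW", task="locations", k=max_edit)
    # several co-optimal spans can exist (e.g. a terminal substitution also
    # admits a deletion alignment); prefer the span closest to barcode length
    start, stop = min(
        loc["locations"],
        key=lambda se: (abs((se[1] - se[0] + 1) - wl.length), se[1]),
    )
    end = stop + 1  # end of the matched span, exclusive
    return _finalize(
        scan.read_id, barcode, best_distance, region[end : end + umi_len],
        umi_whitelist, max_edit,
    )


def _finalize(
    read_id, barcode, distance, raw_umi, umi_whitelist, max_edit
) -> BarcodeAssignment:
    if umi_whitelist is None:
        return BarcodeAssignment(read_id, "assigned", barcode, raw_umi, distance)
    umi = match_umi(raw_umi, umi_whitelist.get(barcode, ()), max_edit)
    if umi is None:
        return BarcodeAssignment(read_id, "unmatched", bc_edit_distance=distance)
    return BarcodeAssignment(read_id, "assigned", barcode, umi, distance)


def build_umi_whitelist(source) -> dict[str, frozenset[str]]:
    """Per-cell known-UMI sets from a TSV path (barcode<TAB>umi) or pairs."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            pairs = [line.split("\t")[:2] for line in fh.read().splitlines() if line.strip()]
    else:
        pairs = [(bc, umi) for bc, umi in source]
    out: dict[str, set[str]] = {}
    for bc, umi in pairs:
        out.setdefault(bc.strip(), set()).add(umi.strip())
    if not out:
        raise ValueError("UMI whitelist source is empty")
    return {bc: frozenset(umis) for bc, umis in out.items()}


def demux_scans(
    scans: Iterable[ScanResult],
    wl: Whitelist,
    max_edit: int = 1,
    *,
    umi_len: int = 12,
    umi_whitelist: "dict[str, frozenset[str]] | None" = None,
) -> Iterator[BarcodeAssignment]:
    for scan in scans:
        if scan.kept:
            yield assign_barcode(
                scan, wl, max_edit, umi_len=umi_len, umi_whitelist=umi_whitelist
            )


def write_assignments_tsv(assignments: Iterable[BarcodeAssignment], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["read_id", "status", "barcode", "umi", "distance"])
        for a in assignments:
            writer.writerow(
                [a.read_id, a.status, a.cell_barcode or "", a.umi or "",
                 "" if a.bc_edit_distance is None else a.bc_edit_distance]
            )
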