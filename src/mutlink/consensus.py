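"""UMI-group consensus calling to suppress per-read sequencing error.

Reads sharing a cell barcode, a UMI, a gene and (approximately) a mapping
position are copies of one cDNA molecule; laying them out in reference-
anchored columns and voting per column removes most per-read Nanopore errors.
The consensus is emitted together with its reference alignment, which is
derived directly from the voted column layout — the consensus is anchored to
the reference by construction, so no re-mapping round trip is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .align import AlignmentRecord, aligned_columns
from .demux import BarcodeAssignment
from .seq import mean_phred


@dataclass(frozen=True)
class UmiGroup:
    """All reads attributed to one (cell, UMI, gene, position-bin) molecule."""

    cell_barcode: str
    umi: str
    gene: str
    contig: str
    anchor_position: int  # ref_start rounded down to the position bin
    member_read_ids: tuple[str, ...]

    @property
    def key(self) -> tuple[str, str, str, int]:
        return (self.cell_barcode, self.umi, self.gene, self.anchor_position)


@dataclass(frozen=True)
class ConsensusMolecule:
    """Per-group consensus sequence plus its reference anchoring."""

    cell_barcode: str
    umi: str
    gene: str
    contig: str
    anchor_position: int
    sequence: str
    support: int
    ref_start: int
    cigar: tuple[tuple[str, int], ...]
    per_column_votes: Mapping[int, Mapping[str, int]] = field(default_factory=dict)

    @property
    def molecule_id(self) -> str:
        return (
            f"{self.cell_barcode}|{self.umi}|{self.gene}|"
            f"{self.anchor_position}|{self.support}"
        )

    @property
    def alignment(self) -> AlignmentRecord:
        return AlignmentRecord(
            read_id=self.molecule_id,
            contig=self.contig,
            ref_start=self.ref_start,
            cigar=self.cigar,
            gene=self.gene,
        )


def group_reads(
    assignments: Iterable[BarcodeAssignment],
    alignments: Mapping[str, AlignmentRecord] | Iterable[AlignmentRecord],
    position_bin: int = 100,
) -> list[UmiGroup]:
    """Partition assigned, aligned reads into UMI groups.

    Grouping key: (cell barcode, UMI identity, gene, reference-start bin).
    ``position_bin=1`` recovers strict mapping-position identity; the default
    of 100 nt tolerates the few-base start jitter of Nanopore read ends.
    """
    if position_bin < 1:
        raise ValueError("position_bin must be >= 1")
    if not isinstance(alignments, Mapping):
        alignments = {a.read_id: a for a in alignments}
    groups: dict[tuple, list[str]] = {}
    for a in assignments:
        if a.status != "assigned":
            continue
        aln = alignments.get(a.read_id)
        if aln is None:
            continue
        gene = aln.gene or aln.contig
        anchor = (aln.ref_start // position_bin) * position_bin
        key = (a.cell_barcode, a.umi, gene, aln.contig, anchor)
        groups.setdefault(key, []).append(a.read_id)
    return [
        UmiGroup(bc, umi, gene, contig, anchor, tuple(sorted(read_ids)))
        for (bc, umi, gene, contig, anchor), read_ids in sorted(groups.items())
    ]


def column_vote(symbols: Sequence[str], qualities: Sequence[float]) -> str:
    """Plurality vote over one reference column.

    ``symbols`` are the observed per-read symbols ('A'/'C'/'G'/'T'/'-' for a
    deletion); ``qualities`` the mean base quality of the voting read.  Ties
    go to the symbol backed by the highest-quality read; a residual tie
    prefers a base over the deletion symbol (a tie is no evidence for
    deleting, and deletions are the dominant ONT artifact), then the
    lexicographically smallest base.
    """
    counts: dict[str, int] = {}
    best_qual: dict[str, float] = {}
    for sym, qual in zip(symbols, qualities):
        counts[sym] = counts.get(sym, 0) + 1
        if qual > best_qual.get(sym, float("-inf")):
            best_qual[sym] = qual
    top = max(counts.values())
    tied = [s for s, c in counts.items() if c == top]
    if len(tied) == 1:
        return tied[0]
    return min(tied, key=lambda s: (-best_qual[s], s == "-", s))


def build_consensus(
    group: UmiGroup,
    alignments: Mapping[str, AlignmentRecord],
    sequences: Mapping[str, str],
    qualities: Mapping[str, str | None] | None = None,
) -> ConsensusMolecule:
    """Vote a consensus sequence for one UMI group.

    Member reads are laid out in reference-anchored columns through their
    CIGARs.  Each covered reference column takes the plurality symbol among
    {A, C, G, T, deletion}; insertion columns enter the consensus only when a
    strict majority (> support/2) of members carries an insertion at that
    reference gap.  A singleton group passes its aligned sequence through
    unchanged.  The result is permutation-invariant in member order.
    """
    members = group.member_read_ids
    contigs = {alignments[r].contig for r in members}
    if len(contigs) != 1:
        raise ValueError(f"group {group.key} spans multiple contigs: {sorted(contigs)}")

    layouts = []
    for read_id in members:
        cols, ins = aligned_columns(alignments[read_id], sequences[read_id])
        qual = mean_phred(qualities.get(read_id)) if qualities else 0.0
        layouts.append((cols, ins, qual))

    positions = sorted(set().union(*(cols.keys() for cols, _, _ in layouts)))
    votes: dict[int, dict[str, int]] = {}
    chosen: dict[int, str] = {}
    for pos in positions:
        syms = [cols[pos] for cols, _, _ in layouts if pos in cols]
        quals = [q for cols, _, q in layouts if pos in cols]
        counts: dict[str, int] = {}
        for s in syms:
            counts[s] = counts.get(s, 0) + 1
        votes[pos] = counts
        chosen[pos] = column_vote(syms, quals)

    support = len(members)
    insertions: dict[int, str] = {}
    ins_positions = set().union(*(ins.keys() for _, ins, _ in layouts))
    for pos in ins_positions:
        carriers = [(ins[pos], q) for _, ins, q in layouts if pos in ins]
        if 2 * len(carriers) > support:
            counts = {}
            best_q: dict[str, float] = {}
            for s, q in carriers:
                counts[s] = counts.get(s, 0) + 1
                best_q[s] = max(best_q.get(s, float("-inf")), q)
            top = max(counts.values())
            tied = sorted(
                (s for s, c in counts.items() if c == top),
                key=lambda s: (-best_q[s], s),
            )
            insertions[pos] = tied[0]

    # assemble sequence and CIGAR from the voted columns
    seq_parts: list[str] = []
    cigar: list[tuple[str, int]] = []

    def emit(op: str, n: int) -> None:
        if n == 0:
            return
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + n)
        else:
            cigar.append((op, n))

    prev = None
    for pos in positions:
        if prev is not None and pos > prev + 1:
            emit("N", pos - prev - 1)  # interior coverage gap
        if pos in insertions:
            seq_parts.append(insertions[pos])
            emit("I", len(insertions[pos]))
        sym = chosen[pos]
        if sym == "-":
            emit("D", 1)
        else:
            seq_parts.append(sym)
            emit("M", 1)
        prev = pos
    trailing = insertions.get(positions[-1] + 1) if positions else None
    if trailing:
        seq_parts.append(trailing)
        emit("I", len(trailing))

    # leading/trailing deletions carry no evidence about the molecule: trim
    while cigar and cigar[0][0] in ("D", "N"):
        op, n = cigar.pop(0)
        if op == "D":  # N gaps have no entries in `positions`
            positions = positions[n:]
    ref_start = positions[0] if positions else group.anchor_position
    while cigar and cigar[-1][0] in ("D", "N"):
        cigar.pop()

    return ConsensusMolecule(
        cell_barcode=group.cell_barcode,
        umi=group.umi,
        gene=group.gene,
        contig=group.contig,
        anchor_position=group.anchor_position,
        sequence="".join(seq_parts),
        support=support,
        ref_start=ref_start,
        cigar=tuple(cigar),
        per_column_votes=votes,
    )


def write_consensus_fasta(molecules: Iterable[ConsensusMolecule], path) -> None:
    with open(path, "w") as fh:
        for mol in molecules:
            fh.write(f">{mol.molecule_id}\n{mol.sequence}\n")


def write_consensus_tsv(molecules: Iterable[ConsensusMolecule], path) -> None:
    import csv

    from .align import cigar_string

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["cell_barcode", "umi", "gene", "contig", "anchor", "support",
             "ref_start", "cigar", "length"]
        )
        for m in molecules:
            writer.writerow(
                [m.cell_barcode, m.umi, m.gene, m.contig, m.anchor_position,
                 m.support, m.ref_start, cigar_string(m.cigar), len(m.sequence)]
            )
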