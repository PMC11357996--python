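"""Per-molecule allele calls and the three-way per-cell mutation status.

Every consensus molecule is interrogated at each target variant site through
its reference alignment; the per-cell aggregate follows the detection rule
used for somatic CHIP genotyping: a cell is *mutated* if the mutant allele is
seen at all (alone or together with the wild-type allele), *non-mutated* if
only wild-type alleles are seen, and *no-coverage* if no molecule spans the
site.  Bases that are neither the reference nor the alternate allele count as
coverage but never as mutant evidence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .align import AlignmentRecord, aligned_columns

STATUSES = ("mutated", "non_mutated", "no_coverage")


@dataclass(frozen=True)
class VariantSite:
    """One target variant: contig, 1-based position, ref and alt alleles."""

    contig: str
    pos: int
    ref_allele: str
    alt_allele: str
    label: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("variant position must be >= 1 (1-based)")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        if not self.ref_allele or not self.alt_allele:
            raise ValueError("empty allele; use anchored VCF-style alleles")
        if self.label is None:
            object.__setattr__(
                self, "label",
                f"{self.contig}:{self.pos}{self.ref_allele}>{self.alt_allele}",
            )

    @property
    def kind(self) -> str:
        if len(self.ref_allele) == len(self.alt_allele) == 1:
            return "SNV"
        if len(self.ref_allele) > len(self.alt_allele):
            return "deletion"
        if len(self.alt_allele) > len(self.ref_allele):
            return "insertion"
        return "MNV"


@dataclass(frozen=True)
class AlleleCall:
    """The allele observed for one molecule at one site."""

    molecule_id: str
    site: str
    call: str  # "ref" | "alt" | "other" | "none"


def call_molecule(mol, aln: AlignmentRecord, site: VariantSite) -> AlleleCall:
    """Call the allele of one aligned (consensus) molecule at a variant site.

    ``mol`` may be a ConsensusMolecule or any object with ``sequence`` and
    ``molecule_id``/``read_id`` attributes (or a plain string).  SNVs compare
    the projected base; deletion alleles require the VCF-deleted reference
    span to be absent from the alignment; insertion alleles require the
    alt-defined bases to be inserted adjacent to the anchor position.
    """
    sequence = mol if isinstance(mol, str) else mol.sequence
    mol_id = getattr(mol, "molecule_id", getattr(mol, "read_id", aln.read_id))
    if site.contig != aln.contig:
        return AlleleCall(mol_id, site.label, "none")
    cols, ins = aligned_columns(aln, sequence)

    if site.kind == "SNV":
        base = cols.get(site.pos)
        if base is None or base == "-":
            call = "none"
        elif base == site.alt_allele:
            call = "alt"
        elif base == site.ref_allele:
            call = "ref"
        else:
            call = "other"
        return AlleleCall(mol_id, site.label, call)

    if site.kind == "deletion":
        anchor = len(site.alt_allele)
        span = range(site.pos + anchor, site.pos + len(site.ref_allele))
        observed = [cols.get(p) for p in span]
        if any(o is None for o in observed):
            call = "none"
        elif all(o == "-" for o in observed):
            call = "alt"
        elif "".join(observed) == site.ref_allele[anchor:]:
            call = "ref"
        else:
            call = "other"
        return AlleleCall(mol_id, site.label, call)

    if site.kind == "insertion":
        anchor_end = site.pos + len(site.ref_allele)
        inserted = site.alt_allele[len(site.ref_allele):]
        anchor_base = cols.get(site.pos)
        observed_ins = ins.get(anchor_end) or ins.get(site.pos)
        if anchor_base is None:
            call = "none"
        elif observed_ins == inserted:
            call = "alt"
        elif observed_ins is not None:
            call = "other"
        elif anchor_base == site.ref_allele[0]:
            call = "ref"
        else:
            call = "other"
        return AlleleCall(mol_id, site.label, call)

    # MNV: compare the projected span verbatim
    observed = [cols.get(p) for p in range(site.pos, site.pos + len(site.ref_allele))]
    if any(o is None or o == "-" for o in observed):
        call = "none"
    elif "".join(observed) == site.alt_allele:
        call = "alt"
    elif "".join(observed) == site.ref_allele:
        call = "ref"
    else:
        call = "other"
    return AlleleCall(mol_id, site.label, call)


@dataclass(frozen=True)
class CellGenotype:
    """Per-cell, per-site mutation status with the supporting molecule counts."""

    cell_barcode: str
    site: str
    status: str
    n_alt_molecules: int = 0
    n_ref_molecules: int = 0
    n_other_molecules: int = 0


def classify_cell(
    cell_barcode: str,
    site: str,
    calls: Sequence[AlleleCall | str],
    min_alt_molecules: int = 1,
) -> CellGenotype:
    """Aggregate a cell's molecule calls at one site into a three-way status.

    mutated     : >= ``min_alt_molecules`` mutant-allele molecules (with or
                  without wild-type molecules alongside);
    no_coverage : no molecule covered the site;
    non_mutated : covered, but below the mutant-molecule threshold.

    'other' alleles count toward coverage but never toward mutant evidence;
    'none' calls carry no coverage.
    """
    values = [c.call if isinstance(c, AlleleCall) else c for c in calls]
    n_alt = values.count("alt")
    n_ref = values.count("ref")
    n_other = values.count("other")
    if n_alt >= min_alt_molecules:
        status = "mutated"
    elif n_alt == n_ref == n_other == 0:
        status = "no_coverage"
    else:
        status = "non_mutated"
    return CellGenotype(cell_barcode, site, status, n_alt, n_ref, n_other)


@dataclass
class MutationMatrix:
    """Cells x sites grid of mutation statuses, ordered like the expression barcodes."""

    table: pd.DataFrame  # columns: cell_barcode, site, status, n_alt, n_ref, n_other

    @property
    def sites(self) -> list[str]:
        return list(dict.fromkeys(self.table["site"]))

    @property
    def barcodes(self) -> list[str]:
        return list(dict.fromkeys(self.table["cell_barcode"]))

    def status_counts(self, site: str) -> dict[str, int]:
        sub = self.table[self.table["site"] == site]
        counts = sub["status"].value_counts().to_dict()
        return {s: int(counts.get(s, 0)) for s in STATUSES}

    def statuses(self, site: str) -> pd.Series:
        sub = self.table[self.table["site"] == site]
        return sub.set_index("cell_barcode")["status"]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "MutationMatrix":
        table = pd.read_csv(
            path, sep="\t",
            dtype={"cell_barcode": str, "site": str, "status": str},
        )
        return cls(table)


def build_mutation_matrix(
    genotypes: Iterable[CellGenotype],
    barcodes: Sequence[str],
) -> MutationMatrix:
    """Join per-cell genotypes onto the expression barcode universe.

    The expression barcodes define the cell universe and the row order; cells
    without genotype evidence become no_coverage; genotyped barcodes absent
    from the expression data are dropped with a warning.  Conflicting
    duplicate (cell, site) statuses are rejected.
    """
    genotypes = list(genotypes)
    universe = set(barcodes)
    seen: dict[tuple[str, str], CellGenotype] = {}
    dropped = 0
    for g in genotypes:
        if g.cell_barcode not in universe:
            dropped += 1
            continue
        key = (g.cell_barcode, g.site)
        if key in seen and seen[key].status != g.status:
            raise ValueError(
                f"conflicting duplicate genotype for cell {g.cell_barcode} "
                f"at {g.site}: {seen[key].status} vs {g.status}"
            )
        seen[key] = g
    if dropped:
        warnings.warn(
            f"{dropped} genotyped barcode(s) absent from the expression "
            "barcode list were dropped",
            stacklevel=2,
        )
    sites = list(dict.fromkeys(g.site for g in genotypes)) or []
    rows = []
    for site in sites:
        for bc in barcodes:
            g = seen.get((bc, site), CellGenotype(bc, site, "no_coverage"))
            rows.append(
                (bc, site, g.status, g.n_alt_molecules, g.n_ref_molecules,
                 g.n_other_molecules)
            )
    table = pd.DataFrame(
        rows,
        columns=["cell_barcode", "site", "status", "n_alt", "n_ref", "n_other"],
    )
    return MutationMatrix(table)


@dataclass(frozen=True)
class MutationFrequency:
    """Observed mutated-cell fraction at one site (no-coverage cells excluded)."""

    frequency: float
    allele_frequency_estimate: float  # frequency/2: heterozygous-clone VAF scale
    n_mutated: int
    n_non_mutated: int
    n_no_coverage: int


def observed_mutation_frequency(matrix: MutationMatrix, site: str) -> MutationFrequency:
    counts = matrix.status_counts(site)
    covered = counts["mutated"] + counts["non_mutated"]
    if covered == 0:
        raise ValueError(f"no covered cells at site {site}: frequency undefined")
    freq = counts["mutated"] / covered
    return MutationFrequency(
        frequency=freq,
        allele_frequency_estimate=freq / 2.0,
        n_mutated=counts["mutated"],
        n_non_mutated=counts["non_mutated"],
        n_no_coverage=counts["no_coverage"],
    )


def read_sites(path) -> list[VariantSite]:
    """Read variant sites from a minimal VCF (CHROM POS ID REF ALT) or a TSV.

    Lines starting with '#' are skipped.  A TSV needs columns
    contig/pos/ref/alt (header optional, order fixed), with an optional label.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rows.append(line.split("\t"))
    if not rows:
        raise ValueError(f"no variant records in {path}")
    sites = []
    for row in rows:
        if row[0].lower() in ("contig", "chrom"):  # header line
            continue
        if path.suffix.lower() == ".vcf" or len(row) >= 5 and row[2] in (".", "") or len(row) >= 8:
            contig, pos, vid, ref, alt = row[:5]
            label = vid if vid not in (".", "") else None
        else:
            contig, pos, ref, alt = row[:4]
            label = row[4] if len(row) > 4 else None
        sites.append(VariantSite(contig, int(pos), ref.upper(), alt.upper(), label))
    return sites
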