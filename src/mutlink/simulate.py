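"""Synthetic barcoded long reads, whitelists, truth tables and expression matrices.

The generator emulates what the pipeline sees after a 10x 3' v3 library is
target-enriched and Nanopore-sequenced: each cDNA molecule becomes one or
more reads of the form

    R1 adapter + 16-nt cell barcode + 12-nt UMI + poly-A tract + cDNA + TSO

optionally reverse-complemented (strand of sequencing is random), with
i.i.d. per-base substitution / insertion / deletion errors.  A configurable
fraction of cells belongs to a mutant clone; clone cells are heterozygous, so
each of their cDNA molecules carries the alternate allele with probability
``het_alt_prob`` (0.5 by default, matching the ~2xVAF cell fraction expected
for heterozygous CHIP clones).  The truth table records the exact pre-error
content of every read and, per cell, the genotype that the emitted molecules
make identifiable.

The error model is deliberately simple — independent per-base events, no
homopolymer awareness — which is exactly what is needed to exercise
edit-distance-1 demultiplexing and per-column consensus voting.  Default
rates (sub 0.03, ins 0.01, del 0.01) approximate a usable Nanopore read while
keeping distance-1 barcode recovery plausible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .genotype import VariantSite

_BASES = np.array(list("ACGT"))
_LUT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _LUT[ord(_b)] = _i


@dataclass(frozen=True)
class ReadStructure:
    """Layout of a 10x 3' v3 barcoded read (adapter-first orientation)."""

    adapter_r1: str = "CTACACGACGCTCTTCCGATCT"
    tso: str = "AAGCAGTGGTATCAACGCAGAGTACAT"
    barcode_len: int = 16
    umi_len: int = 12
    polya_len: int = 30

    def __post_init__(self) -> None:
        if self.barcode_len <= 0 or self.umi_len <= 0:
            raise ValueError("barcode_len and umi_len must be positive")
        for name in ("adapter_r1", "tso"):
            seq = getattr(self, name)
            if not seq or set(seq) - set("ACGT"):
                raise ValueError(f"{name} must be a non-empty string over ACGT")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of one simulated dataset; ``seed`` fixes all randomness."""

    n_cells: int = 200
    clone_fraction: float = 0.1
    sites: tuple[VariantSite, ...] = ()
    umis_per_cell_per_gene: int = 2
    reads_per_umi: int = 3
    sub_rate: float = 0.03
    ins_rate: float = 0.01
    del_rate: float = 0.01
    antisense_fraction: float = 0.5
    het_alt_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sub_rate", "ins_rate", "del_rate"):
            rate = getattr(self, name)
            if not (0 <= rate < 1):
                raise ValueError(f"{name} must be in [0, 1)")
        for name in ("clone_fraction", "antisense_fraction", "het_alt_prob"):
            p = getattr(self, name)
            if not (0 <= p <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if isinstance(self.sites, list):
            object.__setattr__(self, "sites", tuple(self.sites))


@dataclass
class TruthTable:
    """Exact pre-error record of what was simulated.

    ``cells``: barcode, clone membership.  ``cell_sites``: per (cell, site)
    the number of alt molecules actually emitted and the *identifiable*
    expected status (a clone cell that emitted no alt molecule cannot be
    distinguished from wild type by any downstream method and is therefore
    expected non_mutated).  ``reads``: per-read true barcode, UMI, haplotype
    and orientation.
    """

    cells: pd.DataFrame
    cell_sites: pd.DataFrame
    reads: pd.DataFrame

    def expected_status(self, barcode: str, site: str) -> str:
        sub = self.cell_sites
        row = sub[(sub["barcode"] == barcode) & (sub["site"] == site)]
        return row["expected_status"].iloc[0]

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        self.cells.to_csv(out / "truth_cells.tsv", sep="\t", index=False)
        self.cell_sites.to_csv(out / "truth_cell_sites.tsv", sep="\t", index=False)
        self.reads.to_csv(out / "truth_reads.tsv", sep="\t", index=False)


@dataclass
class SimulatedDataset:
    reads: list  # of readscan.LongRead
    whitelist: list[str]
    truth: TruthTable
    reference: Mapping[str, str]
    structure: ReadStructure
    config: SimConfig

    def umi_whitelist(self) -> dict[str, frozenset[str]]:
        """Per-cell true UMI sets — what the short-read library would report."""
        pairs = self.truth.reads[["barcode", "umi"]].drop_duplicates()
        out: dict[str, set[str]] = {}
        for row in pairs.itertuples():
            out.setdefault(row.barcode, set()).add(row.umi)
        return {bc: frozenset(umis) for bc, umis in out.items()}


def random_reference(
    contigs: Sequence[str], length: int = 1200, seed: int = 0
) -> dict[str, str]:
    """Random transcript-level reference sequences (one per contig)."""
    rng = np.random.default_rng(seed)
    return {c: "".join(rng.choice(_BASES, size=length)) for c in contigs}


def _random_kmers(rng: np.random.Generator, n: int, k: int) -> list[str]:
    out: set[str] = set()
    while len(out) < n:
        block = rng.integers(0, 4, size=(n - len(out) + 8, k))
        for row in block:
            out.add("".join(_BASES[row]))
            if len(out) == n:
                break
    return sorted(out)


def mutate_sequence(
    seq: str, rng: np.random.Generator, sub_rate: float, ins_rate: float, del_rate: float
) -> str:
    """Apply i.i.d. per-base substitution / insertion / deletion errors.

    Substitutions are uniform over the three alternative bases; insertions
    add one uniform base after the current one; deletions drop the base.
    """
    if sub_rate == ins_rate == del_rate == 0:
        return seq
    idx = _LUT[np.frombuffer(seq.encode(), dtype=np.uint8)].astype(np.int64)
    n = idx.size
    keep = rng.random(n) >= del_rate
    sub = rng.random(n) < sub_rate
    shift = rng.integers(1, 4, size=n)
    idx = np.where(sub, (idx + shift) % 4, idx)
    ins = rng.random(n) < ins_rate
    ins_base = _BASES[rng.integers(0, 4, size=n)]
    chars = np.where(keep, _BASES[idx], "")
    chars = np.char.add(chars, np.where(ins, ins_base, ""))
    return "".join(chars.tolist())


def apply_variants(sequence: str, variants: Sequence[VariantSite]) -> str:
    """Apply VCF-style variants (descending position keeps coordinates valid)."""
    seq = sequence
    for site in sorted(variants, key=lambda s: -s.pos):
        start = site.pos - 1
        if seq[start : start + len(site.ref_allele)] != site.ref_allele:
            raise ValueError(
                f"reference does not carry {site.ref_allele!r} at "
                f"{site.contig}:{site.pos}"
            )
        seq = seq[:start] + site.alt_allele + seq[start + len(site.ref_allele):]
    return seq


def simulate_dataset(
    cfg: SimConfig,
    reference: Mapping[str, str] | str | Path,
    structure: ReadStructure | None = None,
    out_dir: str | Path | None = None,
) -> SimulatedDataset:
    """Generate reads, whitelist and truth table for one synthetic experiment.

    Every simulated barcode appears in the emitted whitelist; genotypes are
    consistent across all reads of a cell; the truth table records pre-error
    content exactly.  With ``out_dir`` set, reads.fastq, whitelist.tsv, the
    truth TSVs and a perfect-alignment SAM of the error-free cDNA bodies
    (usable instead of an aligner in zero-error runs) are written.
    """
    from .readscan import LongRead  # deferred: readscan imports ReadStructure

    structure = structure or ReadStructure()
    if isinstance(reference, (str, Path)):
        reference = load_fasta(reference)
    for site in cfg.sites:
        if site.contig not in reference:
            raise ValueError(f"site contig {site.contig!r} absent from reference")
        if site.pos + len(site.ref_allele) - 1 > len(reference[site.contig]):
            raise ValueError(f"site {site.label} lies outside its reference contig")

    rng = np.random.default_rng(cfg.seed)
    barcodes = _random_kmers(rng, cfg.n_cells, structure.barcode_len)
    clone = rng.random(cfg.n_cells) < cfg.clone_fraction
    sites_by_contig: dict[str, list[VariantSite]] = {}
    for site in cfg.sites:
        sites_by_contig.setdefault(site.contig, []).append(site)
    contigs = sorted(sites_by_contig) or sorted(reference)

    reads: list = []
    read_rows = []
    cell_site_alt: dict[tuple[str, str], list[int]] = {
        (bc, site.label): [0, 0] for bc in barcodes for site in cfg.sites
    }
    used_umis: set[str] = set()
    polya = "A" * structure.polya_len

    for ci, bc in enumerate(barcodes):
        for contig in contigs:
            contig_sites = sites_by_contig.get(contig, [])
            ref_seq = reference[contig]
            alt_seq = apply_variants(ref_seq, contig_sites) if contig_sites else ref_seq
            for _ in range(cfg.umis_per_cell_per_gene):
                while True:  # UMIs unique within the run: identity grouping is exact
                    umi = "".join(_BASES[rng.integers(0, 4, size=structure.umi_len)])
                    if umi not in used_umis:
                        used_umis.add(umi)
                        break
                is_alt = bool(clone[ci]) and rng.random() < cfg.het_alt_prob
                cdna = alt_seq if is_alt else ref_seq
                for site in contig_sites:
                    counts = cell_site_alt[(bc, site.label)]
                    counts[0] += int(is_alt)
                    counts[1] += 1
                molecule = (
                    structure.adapter_r1 + bc + umi + polya + cdna + structure.tso
                )
                for _ in range(cfg.reads_per_umi):
                    errored = mutate_sequence(
                        molecule, rng, cfg.sub_rate, cfg.ins_rate, cfg.del_rate
                    )
                    antisense = rng.random() < cfg.antisense_fraction
                    if antisense:
                        from .seq import revcomp

                        errored = revcomp(errored)
                    read_id = f"r{len(reads):06d}"
                    reads.append(LongRead(read_id, errored, "I" * len(errored)))
                    read_rows.append(
                        (read_id, bc, umi, contig,
                         "alt" if is_alt else "ref",
                         "antisense" if antisense else "sense")
                    )

    cells = pd.DataFrame({"barcode": barcodes, "clone": clone})
    cs_rows = []
    for bc in barcodes:
        for site in cfg.sites:
            n_alt, n_mol = cell_site_alt[(bc, site.label)]
            if n_mol == 0:
                status = "no_coverage"
            elif n_alt > 0:
                status = "mutated"
            else:
                status = "non_mutated"
            cs_rows.append((bc, site.label, n_alt, n_mol, status))
    cell_sites = pd.DataFrame(
        cs_rows, columns=["barcode", "site", "n_alt_molecules", "n_molecules",
                          "expected_status"],
    )
    read_table = pd.DataFrame(
        read_rows, columns=["read_id", "barcode", "umi", "contig", "allele",
                            "orientation"],
    )
    truth = TruthTable(cells, cell_sites, read_table)
    dataset = SimulatedDataset(reads, barcodes, truth, dict(reference), structure, cfg)
    if out_dir is not None:
        write_dataset(dataset, out_dir)
    return dataset


def write_dataset(dataset: SimulatedDataset, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "reads.fastq", "w") as fh:
        for read in dataset.reads:
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{read.quality}\n")
    (out / "whitelist.tsv").write_text("".join(f"{b}\n" for b in dataset.whitelist))
    umi_wl = dataset.umi_whitelist()
    (out / "umi_whitelist.tsv").write_text(
        "".join(
            f"{bc}\t{umi}\n" for bc in sorted(umi_wl) for umi in sorted(umi_wl[bc])
        )
    )
    dataset.truth.write(out)
    with open(out / "reference.fasta", "w") as fh:
        for contig in sorted(dataset.reference):
            fh.write(f">{contig}\n{dataset.reference[contig]}\n")
    _write_hint_sam(dataset, out / "alignments_hint.sam")


def _write_hint_sam(dataset: SimulatedDataset, path) -> None:
    """True (pre-error) cDNA-body alignments; exact only for zero-error runs."""
    sites_by_contig: dict[str, list[VariantSite]] = {}
    for site in dataset.config.sites:
        sites_by_contig.setdefault(site.contig, []).append(site)
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for contig in sorted(dataset.reference):
            fh.write(f"@SQ\tSN:{contig}\tLN:{len(dataset.reference[contig])}\n")
        for row in dataset.truth.reads.itertuples():
            ref_seq = dataset.reference[row.contig]
            cdna = (
                apply_variants(ref_seq, sites_by_contig.get(row.contig, []))
                if row.allele == "alt"
                else ref_seq
            )
            fh.write(
                f"{row.read_id}\t0\t{row.contig}\t1\t60\t{len(cdna)}M\t*\t0\t0\t"
                f"{cdna}\t{'I' * len(cdna)}\tGE:Z:{row.contig}\n"
            )


def load_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def simulate_expression(
    n_cells: int,
    n_genes: int,
    seed: int = 0,
    *,
    barcodes: Sequence[str] | None = None,
    mean_depth: float = 2000.0,
    boosted_barcodes: Sequence[str] | None = None,
    boosted_genes: Sequence[int] | None = None,
    fold: float = 1.0,
    out_dir: str | Path | None = None,
):
    """Synthetic 10x-style count matrix (genes x cells, non-negative integers).

    Gene abundances are gamma-distributed, cell library sizes log-normal, and
    counts Poisson given both — the usual overdispersed count structure.
    ``boosted_genes``/``boosted_barcodes``/``fold`` multiply the expected
    expression of a gene set in a cell subset, planting a known differential
    signal for recovery experiments.
    """
    from .integrate import ExpressionMatrix, write_expression

    if n_cells < 1 or n_genes < 1:
        raise ValueError("n_cells and n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    if barcodes is None:
        barcodes = _random_kmers(rng, n_cells, 16)
    elif len(barcodes) != n_cells:
        raise ValueError("len(barcodes) must equal n_cells")
    rel = rng.gamma(shape=2.0, scale=1.0, size=n_genes)
    rel /= rel.sum()
    depth = mean_depth * rng.lognormal(mean=0.0, sigma=0.25, size=n_cells)
    lam = np.outer(rel, depth)
    if boosted_genes is not None and boosted_barcodes is not None and fold != 1.0:
        cols = [i for i, b in enumerate(barcodes) if b in set(boosted_barcodes)]
        lam[np.ix_(list(boosted_genes), cols)] *= fold
    counts = rng.poisson(lam)
    features = [(f"G{i:05d}", f"GENE{i}") for i in range(n_genes)]
    expr = ExpressionMatrix(sp.csr_matrix(counts), list(barcodes), features)
    if out_dir is not None:
        write_expression(expr, out_dir)
    return expr
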