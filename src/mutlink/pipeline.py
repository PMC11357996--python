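"""End-to-end orchestration: scan -> demux -> align -> consensus -> genotype -> integrate.

Stages communicate through on-disk TSV/FASTQ/SAM artifacts in the output
directory, so any intermediate can be inspected or re-used; a JSON run report
collects per-stage counts.  A run is fully determined by its configuration
and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import align, consensus, demux, genotype, integrate, readscan, simulate

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated inputs and stage parameters of one pipeline run."""

    fastq: Path
    whitelist: Path
    sites: Path
    umi_whitelist: Path | None = None  # optional barcode<TAB>umi TSV
    reference: Path | None = None  # transcript FASTA for the built-in aligner
    sam: Path | None = None  # pre-computed alignments (external aligner)
    expression_dir: Path | None = None
    targets_bed: Path | None = None
    out_dir: Path = Path("mutlink_out")
    seed: int = 0
    scan_params: dict = field(default_factory=dict)
    max_edit: int = 1
    umi_len: int = 12
    position_bin: int = 100
    min_alt_molecules: int = 1
    min_genes: int = 200
    scale_factor: float = integrate.DEFAULT_SCALE_FACTOR
    downsample: int | str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**{k: v for k, v in raw.items()})
        return cfg

    def __post_init__(self) -> None:
        for name in ("fastq", "whitelist", "sites", "umi_whitelist", "reference",
                     "sam", "expression_dir", "targets_bed"):
            value = getattr(self, name)
            if value is not None:
                setattr(self, name, Path(value))
        self.out_dir = Path(self.out_dir)
        missing = [
            name
            for name in ("fastq", "whitelist", "sites")
            if getattr(self, name) is None or not Path(getattr(self, name)).exists()
        ]
        for name in ("umi_whitelist", "reference", "sam", "expression_dir", "targets_bed"):
            value = getattr(self, name)
            if value is not None and not value.exists():
                missing.append(name)
        if missing:
            raise FileNotFoundError(
                f"missing or nonexistent input path(s): {', '.join(missing)}"
            )
        if self.reference is None and self.sam is None:
            raise ValueError("either 'reference' (built-in aligner) or 'sam' is required")


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Run every stage, write all artifacts, and return the run report."""
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"seed": cfg.seed, "stages": {}}

    # --- scan ------------------------------------------------------------
    reads = list(readscan.read_fastq(cfg.fastq))
    scans = [readscan.scan_read(r, **cfg.scan_params) for r in reads]
    readscan.write_scan_tsv(scans, out / "scan.tsv")
    readscan.write_kept_fastq(scans, out / "kept.fastq")
    kept = [s for s in scans if s.kept]
    report["stages"]["scan"] = {
        "reads_total": len(reads),
        "reads_kept": len(kept),
        "drop_reasons": _count(s.reason for s in scans if not s.kept),
    }
    logger.info("scan: %d/%d reads kept", len(kept), len(reads))

    # --- demux -----------------------------------------------------------
    wl = demux.build_whitelist(cfg.whitelist)
    umi_wl = (
        demux.build_umi_whitelist(cfg.umi_whitelist)
        if cfg.umi_whitelist is not None
        else None
    )
    assignments = [
        demux.assign_barcode(
            s, wl, cfg.max_edit, umi_len=cfg.umi_len, umi_whitelist=umi_wl
        )
        for s in kept
    ]
    demux.write_assignments_tsv(assignments, out / "assignments.tsv")
    by_status = _count(a.status for a in assignments)
    report["stages"]["demux"] = {"whitelist_size": len(wl), **by_status}
    logger.info("demux: %s", by_status)
    assigned_ids = {a.read_id for a in assignments if a.status == "assigned"}

    # --- align -----------------------------------------------------------
    scan_by_id = {s.read_id: s for s in kept}
    sequences: dict[str, str] = {}
    qualities: dict[str, str | None] = {}
    alignments: dict[str, align.AlignmentRecord] = {}
    if cfg.sam is not None:
        for rec in align.parse_sam(cfg.sam):
            if rec.read_id in assigned_ids and rec.read_id not in alignments:
                alignments[rec.read_id] = rec
        for read_id, seq in align.read_sam_sequences(cfg.sam).items():
            if read_id in alignments:
                sequences[read_id] = seq
                qualities[read_id] = None
    else:
        reference = simulate.load_fasta(cfg.reference)
        for read_id in sorted(assigned_ids):
            scan = scan_by_id[read_id]
            cdna = scan.oriented_sequence[scan.cdna_start :]
            qual = (
                scan.oriented_quality[scan.cdna_start :]
                if scan.oriented_quality
                else None
            )
            rec = align.toy_align_best(cdna, reference, read_id=read_id)
            if rec is not None:
                alignments[read_id] = rec
                sequences[read_id] = cdna
                qualities[read_id] = qual
    align.write_alignments_tsv(
        [alignments[r] for r in sorted(alignments)], out / "alignments.tsv"
    )
    report["stages"]["align"] = {"reads_aligned": len(alignments)}

    # --- consensus -------------------------------------------------------
    groups = consensus.group_reads(assignments, alignments, cfg.position_bin)
    molecules = [
        consensus.build_consensus(g, alignments, sequences, qualities) for g in groups
    ]
    consensus.write_consensus_fasta(molecules, out / "consensus.fasta")
    consensus.write_consensus_tsv(molecules, out / "consensus.tsv")
    report["stages"]["consensus"] = {
        "umi_groups": len(groups),
        "molecules": len(molecules),
    }

    # --- genotype --------------------------------------------------------
    sites = genotype.read_sites(cfg.sites)
    calls_by_cell: dict[tuple[str, str], list[genotype.AlleleCall]] = {}
    for mol in molecules:
        for site in sites:
            call = genotype.call_molecule(mol, mol.alignment, site)
            calls_by_cell.setdefault((mol.cell_barcode, site.label), []).append(call)
    genotypes = [
        genotype.classify_cell(bc, site_label, calls, cfg.min_alt_molecules)
        for (bc, site_label), calls in sorted(calls_by_cell.items())
    ]
    expr = None
    if cfg.expression_dir is not None:
        expr = integrate.read_expression(
            cfg.expression_dir / "matrix.mtx",
            cfg.expression_dir / "barcodes.tsv",
            cfg.expression_dir / "features.tsv",
        )
        universe = expr.barcodes
    else:
        universe = sorted(wl.barcodes)
    matrix = genotype.build_mutation_matrix(genotypes, universe)
    matrix.to_tsv(out / "mutation_matrix.tsv")
    geno_report = {}
    for site in sites:
        counts = matrix.status_counts(site.label)
        entry: dict[str, Any] = dict(counts)
        if counts["mutated"] + counts["non_mutated"] > 0:
            freq = genotype.observed_mutation_frequency(matrix, site.label)
            entry["observed_mutation_frequency"] = freq.frequency
            entry["allele_frequency_estimate"] = freq.allele_frequency_estimate
        geno_report[site.label] = entry
    report["stages"]["genotype"] = geno_report

    # --- integrate -------------------------------------------------------
    if cfg.targets_bed is not None:
        targets = integrate.read_bed(cfg.targets_bed)
        ontarget = integrate.on_target_report(alignments.values(), targets)
        report["stages"]["on_target"] = {
            "aligned": ontarget.n_aligned,
            "on_target": ontarget.n_on_target,
            "fraction": ontarget.on_target_fraction,
        }
    if expr is not None and sites:
        expr_f = integrate.filter_cells(expr, cfg.min_genes)
        norm = integrate.log_normalize(expr_f, cfg.scale_factor)
        site = sites[0]
        statuses = matrix.statuses(site.label)
        mutated = [b for b in norm.barcodes if statuses.get(b) == "mutated"]
        wildtype = [b for b in norm.barcodes if statuses.get(b) == "non_mutated"]
        if cfg.downsample is not None and mutated and wildtype:
            sampled = integrate.downsample_groups(
                {"mutated": mutated, "non_mutated": wildtype},
                cfg.downsample,
                seed=cfg.seed,
            )
            mutated, wildtype = sampled["mutated"], sampled["non_mutated"]
        if len(mutated) >= 3 and len(wildtype) >= 3:
            de = integrate.differential_expression(norm, mutated, wildtype)
            de.to_csv(out / "de_results.tsv", sep="\t", index=False)
            report["stages"]["differential_expression"] = {
                "site": site.label,
                "n_mutated_cells": len(mutated),
                "n_wildtype_cells": len(wildtype),
                "genes_tested": int(len(de)),
                "genes_significant": int(de["significant"].sum()),
            }

    report_text = json.dumps(report, indent=2, sort_keys=True)
    (out / "report.json").write_text(report_text + "\n")
    return report


def _count(items) -> dict[str, int]:
    out: dict[str, int] = {}
    for item in items:
        key = str(item)
        out[key] = out.get(key, 0) + 1
    return dict(sorted(out.items()))
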