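"""Expression-side analysis: QC, normalization, downsampling, DE, on-target QC.

The mutation matrix assigns each profiled cell a mutated / non-mutated /
no-coverage status; this module carries the expression side of the
comparison.  Cells expressing fewer than 200 genes are dropped, counts are
normalized per cell to a scale factor of 10,000 and natural-log transformed
(``ln(1 + count * 10000 / cell_total)``), groups may be downsampled to a
common size to avoid abundance bias, and mutant-vs-wild-type differences are
tested per gene with a two-sided Welch t-test followed by Benjamini-Hochberg
adjustment (significant at adjusted p < 0.05).  A separate QC summarizes how
many aligned long reads fall inside the capture-panel target intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .align import AlignmentRecord

DEFAULT_SCALE_FACTOR = 10_000.0


@dataclass
class ExpressionMatrix:
    """Genes x cells integer count matrix with its barcode and feature lists."""

    counts: sp.csr_matrix  # genes x cells
    barcodes: list[str]
    features: list[tuple[str, str]]  # (gene id, gene symbol)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.features), len(self.barcodes)):
            raise ValueError(
                f"matrix shape {self.counts.shape} does not match "
                f"{len(self.features)} features x {len(self.barcodes)} barcodes"
            )
        if (self.counts.data < 0).any():
            raise ValueError("negative counts")

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    @property
    def n_genes(self) -> int:
        return len(self.features)

    def genes_per_cell(self) -> np.ndarray:
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()


@dataclass
class NormalizedMatrix:
    """ln(1 + count * scale / cell_total) values, genes x cells."""

    values: sp.csr_matrix
    barcodes: list[str]
    features: list[tuple[str, str]]
    scale_factor: float = DEFAULT_SCALE_FACTOR

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())

    def column_index(self, barcodes: Sequence[str]) -> np.ndarray:
        lookup = {b: i for i, b in enumerate(self.barcodes)}
        return np.array([lookup[b] for b in barcodes], dtype=int)


def read_expression(mtx_path, barcodes_path, features_path) -> ExpressionMatrix:
    """Load a 10x-convention triplet: matrix.mtx + barcodes.tsv + features.tsv."""
    counts = sp.csr_matrix(scipy.io.mmread(str(mtx_path)))
    barcodes = [
        line.split("\t")[0].strip()
        for line in Path(barcodes_path).read_text().splitlines()
        if line.strip()
    ]
    features = []
    for line in Path(features_path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        features.append((parts[0], parts[1] if len(parts) > 1 else parts[0]))
    return ExpressionMatrix(counts, barcodes, features)


def write_expression(expr: ExpressionMatrix, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(out / "matrix.mtx"), sp.coo_matrix(expr.counts), field="integer")
    (out / "barcodes.tsv").write_text("".join(f"{b}\n" for b in expr.barcodes))
    (out / "features.tsv").write_text(
        "".join(f"{gid}\t{sym}\tGene Expression\n" for gid, sym in expr.features)
    )


def filter_cells(expr: ExpressionMatrix, min_genes: int = 200) -> ExpressionMatrix:
    """Keep cells expressing at least ``min_genes`` genes (count > 0)."""
    keep = expr.genes_per_cell() >= min_genes
    if not keep.any():
        raise ValueError(f"no cell expresses >= {min_genes} genes")
    return ExpressionMatrix(
        expr.counts[:, keep],
        [b for b, k in zip(expr.barcodes, keep) if k],
        expr.features,
    )


def log_normalize(
    expr: ExpressionMatrix, scale_factor: float = DEFAULT_SCALE_FACTOR
) -> NormalizedMatrix:
    """Per-cell total-count normalization to ``scale_factor``, then ln(1 + x)."""
    totals = np.asarray(expr.counts.sum(axis=0)).ravel().astype(float)
    if (totals == 0).any():
        raise ValueError("cell with zero total count; filter cells first")
    scaled = expr.counts.astype(float).multiply((scale_factor / totals)[None, :])
    values = sp.csr_matrix(scaled)
    values.data = np.log1p(values.data)
    return NormalizedMatrix(values, list(expr.barcodes), list(expr.features), scale_factor)


def downsample_groups(
    cells_by_group: Mapping[str, Sequence[str]],
    target: int | str = "min",
    seed: int = 0,
) -> dict[str, list[str]]:
    """Uniformly downsample every group to a common size, without replacement.

    ``target="min"`` uses the smallest group size.  A group already at the
    target is returned unchanged (no resampling); sampling is seeded and
    reproducible.  Barcodes are never duplicated.
    """
    sizes = {g: len(v) for g, v in cells_by_group.items()}
    n = min(sizes.values()) if target == "min" else int(target)
    if any(size < n for size in sizes.values()):
        raise ValueError(f"target {n} exceeds the smallest group size {min(sizes.values())}")
    rng = np.random.default_rng(seed)
    out: dict[str, list[str]] = {}
    for group in sorted(cells_by_group):
        members = list(cells_by_group[group])
        if len(members) == n:
            out[group] = members
        else:
            idx = rng.choice(len(members), size=n, replace=False)
            out[group] = [members[i] for i in sorted(idx)]
    return out


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (statsmodels-backed)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    norm: NormalizedMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    paired_by: Mapping[str, str] | None = None,
    *,
    alpha: float = 0.05,
    min_cells_per_patient: int = 5,
) -> pd.DataFrame:
    """Per-gene two-sided mutant-vs-wild-type test on normalized values.

    Pooled mode runs a Welch (unequal-variance) t-test per gene across cells.
    Paired mode (``paired_by`` maps barcode -> patient) first averages each
    gene per patient within each group, keeps patients contributing at least
    ``min_cells_per_patient`` cells to both groups, and runs a paired t-test
    across patients.  P-values are Benjamini-Hochberg adjusted across tested
    genes; ``significant`` means adjusted p < ``alpha``.  Genes with zero
    variance in both groups get p = 1 by convention and are flagged.
    """
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"groups are not disjoint ({len(overlap)} shared barcodes)")
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValueError("each group needs >= 3 cells")
    dense = norm.dense()
    a = dense[:, norm.column_index(group_a)]
    b = dense[:, norm.column_index(group_b)]

    if paired_by is None:
        with np.errstate(invalid="ignore", divide="ignore"):
            stat, p = scipy.stats.ttest_ind(a, b, axis=1, equal_var=False)
        mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    else:
        pat_a = pd.Series([paired_by[bc] for bc in group_a])
        pat_b = pd.Series([paired_by[bc] for bc in group_b])
        counts_a, counts_b = pat_a.value_counts(), pat_b.value_counts()
        patients = sorted(
            p_ for p_ in set(counts_a.index) & set(counts_b.index)
            if counts_a[p_] >= min_cells_per_patient
            and counts_b[p_] >= min_cells_per_patient
        )
        if len(patients) < 2:
            raise ValueError("paired mode needs >= 2 patients passing the cell minimum")
        prof_a = np.column_stack([a[:, (pat_a == p_).to_numpy()].mean(axis=1) for p_ in patients])
        prof_b = np.column_stack([b[:, (pat_b == p_).to_numpy()].mean(axis=1) for p_ in patients])
        with np.errstate(invalid="ignore", divide="ignore"):
            stat, p = scipy.stats.ttest_rel(prof_a, prof_b, axis=1)
        mean_a, mean_b = prof_a.mean(axis=1), prof_b.mean(axis=1)

    zero_variance = np.isnan(p)
    p = np.where(zero_variance, 1.0, p)
    stat = np.where(zero_variance, 0.0, stat)
    p_adj = benjamini_hochberg(p)
    mean_diff = mean_a - mean_b
    return pd.DataFrame(
        {
            "gene_id": [f[0] for f in norm.features],
            "gene": [f[1] for f in norm.features],
            "mean_diff": mean_diff,
            "t_statistic": stat,
            "p_value": p,
            "p_adjusted": p_adj,
            "significant": p_adj < alpha,
            "direction": np.where(mean_diff > 0, "up", np.where(mean_diff < 0, "down", "flat")),
            "zero_variance": zero_variance,
        }
    )


@dataclass(frozen=True)
class OnTargetReport:
    """Capture-efficiency QC of the long-read library."""

    per_gene_counts: Mapping[str, int]
    n_aligned: int
    n_on_target: int
    on_target_fraction: float


def read_bed(path) -> list[tuple[str, int, int]]:
    """Half-open 0-based BED intervals (first three columns)."""
    intervals = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        contig, start, end = line.split("\t")[:3]
        intervals.append((contig, int(start), int(end)))
    return intervals


def on_target_report(
    alignments: Iterable[AlignmentRecord],
    targets: Sequence[tuple[str, int, int]],
) -> OnTargetReport:
    """Fraction of aligned reads overlapping any target interval by >= 1 base."""
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for contig, start, end in targets:
        if end > start:
            trees.setdefault(contig, IntervalTree()).addi(start, end)
    n_aligned = 0
    n_on = 0
    per_gene: dict[str, int] = {}
    for aln in alignments:
        n_aligned += 1
        gene = aln.gene or aln.contig
        per_gene[gene] = per_gene.get(gene, 0) + 1
        tree = trees.get(aln.contig)
        # alignment covers [ref_start-1, ref_end) in 0-based half-open coords
        if tree is not None and tree.overlap(aln.ref_start - 1, aln.ref_end):
            n_on += 1
    fraction = n_on / n_aligned if n_aligned else 0.0
    return OnTargetReport(per_gene, n_aligned, n_on, fraction)
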