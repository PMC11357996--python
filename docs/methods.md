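# Methods

## The measurement problem

A heterozygous somatic clone that makes up fraction *c* of a cell population
carries the variant allele at frequency VAF ≈ *c*/2 in bulk DNA. Linking the
variant to single cells requires reading the mutation and the cell barcode on
the same molecule, which is what targeted long-read sequencing of barcoded
full-length cDNA provides. The obstacle is the long-read error rate: a raw
Nanopore read has a few percent per-base error, far above the signal of a
single-nucleotide variant, so the pipeline's job is to concentrate evidence —
first by anchoring each read to a cell (barcode) and molecule (UMI), then by
voting across reads of the same molecule — before calling any allele.

## Read model and the synthetic generator

Simulated reads follow the 10x 3′ v3 layout in sense orientation:

    R1 adapter (22 nt) · barcode (16 nt) · UMI (12 nt) · poly-A (30 nt) · cDNA · TSO

with each read reverse-complemented with probability `antisense_fraction`
(default 0.5; sequencing strand is random). Errors are i.i.d. per base:
substitution (uniform over the 3 alternatives), single-base insertion after
the position, and deletion, at default rates 0.03 / 0.01 / 0.01. This is the
simplest model that exercises edit-distance-1 demultiplexing and per-column
consensus voting; it deliberately omits homopolymer-dependent error,
base-caller quality correlation, splice structure, chimeras and
capture-efficiency variation, so passing tests bound algorithmic behaviour,
not performance on real flow-cell data. The leading `NNN` of the published
enrichment primers is a PCR feature, not read content, and is excluded.

Mutant-clone cells are drawn per cell with probability `clone_fraction`;
being heterozygous, each of their cDNA molecules carries the alt haplotype
with probability `het_alt_prob` (default 0.5). Default molecule counts are 2
UMIs per (cell, gene) and 3 reads per UMI — the sparse regime a targeted
capture of a moderately expressed gene actually yields, and the regime in
which the consensus and classification rules are stressed. The truth table
records exact pre-error read content and, per cell, the *identifiable*
expected status: a clone cell none of whose emitted molecules carried the
alt allele cannot be distinguished from wild type by any downstream method
(with 2 UMIs and het 0.5 this is ~25% of clone cells), so accuracy is
defined against what was emitted, and the observed mutant-cell fraction is
expected to sit slightly below the nominal clone fraction (~0.075 for a 0.10
clone). Expression matrices are gamma–Poisson (overdispersed) counts with
log-normal library sizes; a gene-set/cell-set multiplicative boost plants
known differential signal for recovery experiments.

All randomness flows from one `numpy` `default_rng(seed)`; outputs are
byte-reproducible.

## Scanning and demultiplexing

The adapter is located by semi-global (infix) edit-distance match within the
first `search_window` = 200 nt of the read and of its reverse complement;
the better orientation wins and the read is reported adapter-first. Defaults
`adapter_max_edit` = 3 (≈14% of a 22-mer) and `polya_min_len` = 10 are
engineering choices — the tract and tolerance are not published — set so
error-free reads always pass; keeping fractions are monotone in both, so
they can be tightened against real data.

Barcodes are matched semi-globally against the short-read whitelist inside a
`barcode_len + max_edit` window after the adapter (one indel before or inside
the barcode is tolerated), keeping the unique entry at minimal distance ≤ 1;
distance ties are ambiguous and excluded — conservative, since the original
tie behaviour is undocumented. Among co-optimal alignment spans of the
winning barcode, the span closest to the barcode length is used to place the
UMI (a terminal substitution otherwise masquerades as an indel and shifts
the UMI window by one).

The UMI is the next 12 bases. When the per-cell UMI list from the short-read
library is provided, the raw UMI is matched against the assigned cell's known
UMIs at global edit distance ≤ 1 (unique match required; failures are
dropped). This mirrors the original workflow, in which valid cell barcodes
*and* UMIs are extracted from the short-read alignment and searched with an
allowed edit distance of 1. It matters quantitatively: with 12-nt UMIs at 3%
substitution error roughly a third of reads carry a UMI error, and under
verbatim-UMI identity grouping those reads fragment into unsupported
singleton "molecules" whose residual errors leak into the mutation calls
(end-to-end accuracy ~96–98%); with UMI matching the reads rejoin their
groups and accuracy exceeds 99%. Without a UMI list the verbatim/identity
behaviour is used.

## Alignment and coordinates

Reference positions are 1-based inclusive (SAM/VCF convention), read offsets
0-based. SAM ingestion keeps primary mapped records only and validates each
record's CIGAR against its sequence, skipping and logging inconsistent
records individually. The built-in aligner is edlib's infix mode — free end
gaps on the reference, unit costs — suitable for ungapped transcript
references; reads whose best edit distance exceeds 0.4× their length are
unaligned. In coordinate projection, a deletion run consumes reference and
yields status `deleted`, while an N (spliced-out) run yields `unaligned`:
an intron is absence of coverage, not a deletion allele.

## Consensus

Reads are grouped by (cell barcode, UMI identity, gene, reference-start bin).
"Identical mapping position" is softened to a bin (default 100 nt) because
ONT read ends jitter by a few bases; `position_bin=1` restores strict
identity. Each member is laid out in reference-anchored columns through its
CIGAR; every covered column takes the plurality symbol over
{A, C, G, T, deletion}. Ties go to the symbol backed by the read with the
highest mean base quality; a residual tie prefers a base over a deletion
(a 1–1 tie is no evidence for deleting, and deletions are a dominant ONT
artifact), then the lexicographically smallest base — a deterministic,
member-order-invariant rule. Insertions enter the consensus only when a
strict majority (> support/2) of members carries an insertion at that
reference gap, the inserted sequence being the plurality string among
carriers; rationale: spurious insertions are the most common ONT artifact.
Because the consensus is built in reference-anchored columns, its own
reference alignment (start + CIGAR) is emitted directly from the voted
layout rather than by re-mapping — equivalent by construction and exact.

## Genotyping

Per molecule and site: SNVs compare the projected base (`alt`, `ref`, any
other base `other`, deleted/uncovered `none`); deletion alleles require the
VCF-deleted span to be absent (`alt`) or intact (`ref`); insertion alleles
require the alt-defined bases inserted at the anchor. Per cell, the rule is
verbatim three-way: any alt molecule ⇒ mutated (≥ `min_alt_molecules`,
default 1, exposed because a single alt molecule can be an artifact at high
error rates); no informative molecule ⇒ no-coverage; otherwise non-mutated.
`other` calls count as coverage — "no coverage" means no sequence at the
site, not "no recognised allele". The expression barcode list defines the
cell universe: profiled cells without long-read evidence are no-coverage,
and genotyped barcodes absent from the expression data are dropped (the
integration joins onto the short-read object).

## Expression comparison

Cells expressing fewer than 200 genes are removed; values are
ln(1 + 10⁴·c/Σc) per cell (natural log; base configurable). Downsampling to
a common group size (default: the smallest group) is uniform without
replacement and seeded. Differential expression uses a per-gene two-sided
Welch t-test (unequal variances; the test family is stated, the variance
assumption is not, and Welch is the robust default), Benjamini–Hochberg
adjusted across tested genes — the de facto default of the stated analysis
stack, exposed as a parameter — with significance at adjusted p < 0.05.
Genes with zero variance in both groups get p = 1 and are flagged. Paired
mode averages each gene per patient within each group, keeps patients
contributing ≥ `min_cells_per_patient` = 5 cells to both groups, and runs a
paired t-test across patients. Regression of expression on per-cell nUMI is
not applied by default; clustering, embedding, annotation, differential
abundance and ligand–receptor inference are out of scope — group labels
arrive as input.

## DNA variant post-filter

The filter is a pure rule engine over annotated variant tables (calling and
annotation are upstream inputs). VAF = alt/(ref+alt). Exclusions: dbSNP-
common; population MAF ≥ 5% (when annotated); MAPQ < 20; cohort recurrence
≥ 8% of patients (the "8% or more" wording makes the bound inclusive for
exclusion); depth < 100 in either amplicon set; called in only one set;
impact LOW or MODIFIER; VAF < 0.01; VAF in the inclusive germline band
[0.45, 0.55]. Records with missing required annotations are excluded with
reason `missing_annotation`. The audit table names every failing rule per
record; filtering is idempotent and monotone in each threshold.

## Problem sizes and numerical choices

Default test and acceptance runs use 1.2-kb transcript references, 500-cell
simulations with 2 UMIs × 3 reads at the study's 10% clone fraction, 10⁴
demultiplexing oracle instances against whitelists of 10³–10⁴ barcodes, 10⁵
consensus columns, and 1,000-gene × 400-cell expression matrices — sizes at
which every oracle comparison is exhaustive or statistically well-powered
while the whole suite runs in minutes on one CPU. Oracles (pure-DP edit
distance, explicit CIGAR column walks, hand-coded BH step-up, rule-by-rule
filter evaluation, counting votes) share no code with the implementation.

## Known limitations

The error model's independence assumptions understate homopolymer and
strand-correlated ONT error; the toy aligner does not handle introns (real
genome alignments must come from a splice-aware aligner); UMI matching
requires short-read UMIs and otherwise falls back to identity grouping;
multi-site phasing, de novo variant discovery and UMI network collapse are
intentionally not implemented.
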