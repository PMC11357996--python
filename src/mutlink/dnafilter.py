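"""Post-hoc filter rules for targeted DNA-sequencing variant tables.

Upstream calling and annotation (caller, effect predictor, population
databases) are inputs, not computations: each record arrives with its read
counts, mapping quality, per-amplicon-set depths and calls, population allele
frequency and predicted impact.  This module applies the somatic-variant
exclusion rules as an auditable rule engine: every excluded record names the
rule(s) it failed, filtering is idempotent, and every threshold is a
parameter of :class:`FilterRules`.

VAF (variant allele frequency) = alternate reads / (reference + alternate
reads); a heterozygous germline variant sits near VAF 0.5, which is why the
0.45-0.55 band is excluded when hunting somatic CHIP variants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd


@dataclass(frozen=True)
class VariantRecord:
    """One annotated variant call for one patient."""

    patient_id: str
    contig: str
    pos: int
    ref: str
    alt: str
    ref_reads: int
    alt_reads: int
    mapq: int
    depth_catA: int
    depth_catB: int
    called_catA: bool
    called_catB: bool
    dbsnp_common: bool
    impact: str  # HIGH | MODERATE | LOW | MODIFIER
    population_maf: float | None = None

    @property
    def vaf(self) -> float:
        return compute_vaf(self.ref_reads, self.alt_reads)


@dataclass(frozen=True)
class FilterRules:
    """Thresholds of the somatic-variant post-filter (all exposed as parameters)."""

    vaf_min: float = 0.01
    germline_band: tuple[float, float] = (0.45, 0.55)  # inclusive both ends
    maf_common: float = 0.05
    mapq_min: int = 20
    cohort_recurrence_max: float = 0.08  # exclude at >= this fraction of patients
    min_depth_per_amplicon_set: int = 100
    excluded_impacts: tuple[str, ...] = ("LOW", "MODIFIER")

    def __post_init__(self) -> None:
        lo, hi = self.germline_band
        if not (0 <= self.vaf_min < lo < hi <= 1):
            raise ValueError("require 0 <= vaf_min < germline band lower < upper <= 1")


def compute_vaf(ref_reads: int, alt_reads: int) -> float:
    """alternate reads / (reference + alternate reads)."""
    if ref_reads < 0 or alt_reads < 0:
        raise ValueError("read counts must be non-negative")
    total = ref_reads + alt_reads
    if total == 0:
        raise ValueError("VAF undefined: zero total reads at the site")
    return alt_reads / total

#: rule names in audit order
RULE_NAMES = (
    "missing_annotation",
    "dbsnp_common",
    "population_maf",
    "mapq",
    "cohort_recurrence",
    "min_depth",
    "single_amplicon_set",
    "impact",
    "vaf_undefined",
    "vaf_min",
    "germline_band",
)

_REQUIRED = (
    "patient_id", "contig", "pos", "ref", "alt", "ref_reads", "alt_reads",
    "mapq", "depth_catA", "depth_catB", "called_catA", "called_catB",
    "dbsnp_common", "impact",
)


def records_to_frame(records: Sequence[VariantRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def apply_filters(
    records: Sequence[VariantRecord] | pd.DataFrame,
    rules: FilterRules | None = None,
    cohort_size: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply every exclusion rule; return (kept records, per-record audit).

    A record is kept iff it passes ALL rules: not a common dbSNP variant;
    population MAF (when annotated) below ``maf_common``; mapping quality >=
    ``mapq_min``; cohort recurrence (distinct carrier patients / cohort size)
    strictly below ``cohort_recurrence_max``; both amplicon sets covered to
    >= ``min_depth_per_amplicon_set`` and both calling the variant; impact not
    LOW/MODIFIER; VAF defined and >= ``vaf_min``; VAF outside the inclusive
    germline band.  The audit frame has one boolean ``fail_<rule>`` column per
    rule plus ``kept`` and a semicolon-joined ``reasons`` column.
    """
    rules = rules or FilterRules()
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(list(records))
    frame = frame.reset_index(drop=True)
    if cohort_size is None:
        cohort_size = frame["patient_id"].nunique() if len(frame) else 1
    if cohort_size < 1:
        raise ValueError("cohort_size must be >= 1")

    n = len(frame)
    audit = pd.DataFrame(index=frame.index)
    missing = pd.Series(False, index=frame.index)
    for col in _REQUIRED:
        if col not in frame.columns:
            missing |= True
        else:
            missing |= frame[col].isna()
    audit["fail_missing_annotation"] = missing

    def col(name, default=None):
        return frame[name] if name in frame.columns else pd.Series([default] * n, index=frame.index)

    vaf = pd.Series(math.nan, index=frame.index, dtype=float)
    total = col("ref_reads", 0).fillna(0) + col("alt_reads", 0).fillna(0)
    ok = total > 0
    vaf[ok] = col("alt_reads", 0)[ok] / total[ok]
    audit["fail_vaf_undefined"] = ~ok

    audit["fail_dbsnp_common"] = col("dbsnp_common", False).fillna(False).astype(bool)
    maf = pd.to_numeric(col("population_maf"), errors="coerce")
    audit["fail_population_maf"] = maf.notna() & (maf >= rules.maf_common)
    audit["fail_mapq"] = pd.to_numeric(col("mapq"), errors="coerce").fillna(-1) < rules.mapq_min

    variant_key = list(zip(col("contig", ""), col("pos", -1), col("ref", ""), col("alt", "")))
    carriers = (
        pd.DataFrame({"key": variant_key, "patient": col("patient_id", "")})
        .groupby("key")["patient"]
        .nunique()
    )
    recurrence = pd.Series([carriers[k] / cohort_size for k in variant_key], index=frame.index)
    audit["fail_cohort_recurrence"] = recurrence >= rules.cohort_recurrence_max

    depth_ok = (
        (pd.to_numeric(col("depth_catA"), errors="coerce").fillna(-1)
         >= rules.min_depth_per_amplicon_set)
        & (pd.to_numeric(col("depth_catB"), errors="coerce").fillna(-1)
           >= rules.min_depth_per_amplicon_set)
    )
    audit["fail_min_depth"] = ~depth_ok
    audit["fail_single_amplicon_set"] = ~(
        col("called_catA", False).fillna(False).astype(bool)
        & col("called_catB", False).fillna(False).astype(bool)
    )
    audit["fail_impact"] = col("impact", "").isin(rules.excluded_impacts)
    audit["fail_vaf_min"] = ok & (vaf < rules.vaf_min)
    lo, hi = rules.germline_band
    audit["fail_germline_band"] = ok & (vaf >= lo) & (vaf <= hi)

    fail_cols = [f"fail_{r}" for r in RULE_NAMES]
    audit = audit[fail_cols]
    audit["kept"] = ~audit[fail_cols].any(axis=1)
    audit["reasons"] = [
        ";".join(r for r in RULE_NAMES if row[f"fail_{r}"])
        for _, row in audit.iterrows()
    ]
    audit.insert(0, "vaf", vaf)
    kept = frame[audit["kept"]].copy()
    kept["vaf"] = vaf[audit["kept"]]
    return kept, audit
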