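"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written from first principles (plain dynamic
programming, exhaustive scans, hand-applied formulas) and shares no code with
the package, so agreement is evidence rather than tautology.
"""

from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------- edit distance
def edit_distance(a: str, b: str) -> int:
    """Global unit-cost Levenshtein distance, full DP table."""
    n, m = len(a), len(b)
    dp = list(range(m + 1))
    for i in range(1, n + 1):
        prev = dp[0]
        dp[0] = i
        for j in range(1, m + 1):
            cur = dp[j]
            dp[j] = min(dp[j] + 1, dp[j - 1] + 1, prev + (a[i - 1] != b[j - 1]))
            prev = cur
    return dp[m]


def semi_global_distance(query: str, target: str) -> int:
    """Best edit distance of ``query`` against any substring of ``target``.

    Free end gaps on the target (infix/HW semantics): row 0 is all zeros and
    the answer is the minimum of the last row.
    """
    n, m = len(query), len(target)
    dp = [0] * (m + 1)
    for i in range(1, n + 1):
        prev = dp[0]
        dp[0] = i
        for j in range(1, m + 1):
            cur = dp[j]
            dp[j] = min(dp[j] + 1, dp[j - 1] + 1, prev + (query[i - 1] != target[j - 1]))
            prev = cur
    return min(dp)


_ENC = {c: i for i, c in enumerate("ACGT")}


def batch_semi_global_distance(queries: np.ndarray, target: str) -> np.ndarray:
    """Vectorized semi-global DP: one target vs many equal-length queries.

    ``queries`` is an (n_queries, query_len) int array encoding A/C/G/T as
    0..3.  Returns the per-query infix edit distance against ``target``.
    """
    t = np.array([_ENC[c] for c in target], dtype=np.int8)
    n, L = queries.shape
    m = t.size
    dp = np.zeros((n, m + 1), dtype=np.int32)
    for i in range(1, L + 1):
        prev_row = dp.copy()
        dp[:, 0] = i
        mismatch = (queries[:, i - 1 : i] != t[None, :]).astype(np.int32)
        for j in range(1, m + 1):
            dp[:, j] = np.minimum(
                np.minimum(prev_row[:, j] + 1, dp[:, j - 1] + 1),
                prev_row[:, j - 1] + mismatch[:, j - 1],
            )
    return dp.min(axis=1)


def brute_assign(
    target: str, whitelist: list[str], max_edit: int
) -> tuple[str, str | None, int | None]:
    """Exhaustive Levenshtein barcode search: (status, barcode, distance)."""
    distances = {bc: semi_global_distance(bc, target) for bc in whitelist}
    best = min(distances.values())
    if best > max_edit:
        return ("unmatched", None, None)
    hits = [bc for bc, d in distances.items() if d == best]
    if len(hits) > 1:
        return ("ambiguous", None, best)
    return ("assigned", hits[0], best)


# ---------------------------------------------------------------- CIGAR walk
def cigar_column_map(ref_start: int, cigar: list[tuple[str, int]]):
    """Explicit per-position map: ref position -> ('M', read_offset) | ('D'|'N', None)."""
    table = {}
    ref, off = ref_start, 0
    for op, n in cigar:
        for _ in range(n):
            if op == "M":
                table[ref] = ("M", off)
                ref += 1
                off += 1
            elif op in ("I", "S"):
                off += 1
            elif op in ("D", "N"):
                table[ref] = (op, None)
                ref += 1
            # H: nothing
    return table


def project_site_oracle(ref_start, cigar, pos):
    table = cigar_column_map(ref_start, cigar)
    if pos not in table:
        return ("unaligned", None)
    op, off = table[pos]
    if op == "M":
        return ("aligned", off)
    if op == "D":
        return ("deleted", None)
    return ("unaligned", None)


# ---------------------------------------------------------------- statistics
def bh_stepup(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, written out by hand."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(n)
    out[order] = adjusted
    return out


# ---------------------------------------------------------------- voting rules
def column_vote_oracle(symbols, qualities) -> str:
    """Plurality per column; tie -> highest supporting read quality -> a base
    rather than the deletion symbol -> smallest base."""
    from collections import Counter

    counts = Counter(symbols)
    top = max(counts.values())
    tied = sorted(s for s, c in counts.items() if c == top)
    if len(tied) == 1:
        return tied[0]
    scored = []
    for sym in tied:
        qual = max(q for s, q in zip(symbols, qualities) if s == sym)
        scored.append((-qual, sym == "-", sym))
    return min(scored)[2]


def classify_oracle(calls: list[str], min_alt: int = 1) -> str:
    """Verbatim three-way rule over a multiset of molecule calls."""
    informative = [c for c in calls if c in ("ref", "alt", "other")]
    if informative.count("alt") >= min_alt:
        return "mutated"
    if not informative:
        return "no_coverage"
    return "non_mutated"


# ---------------------------------------------------------------- intervals
def overlaps_any(start0: int, end0: int, intervals) -> bool:
    """Brute per-interval scan: half-open [start0, end0) vs half-open targets."""
    return any(s < end0 and start0 < e for (s, e) in intervals)
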