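"""Tiny DNA string helpers shared across modules."""

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def mean_phred(quality: str | None) -> float:
    """Mean Phred score of a Phred+33 quality string; 0.0 when absent."""
    if not quality:
        return 0.0
    return sum(ord(c) - 33 for c in quality) / len(quality)
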