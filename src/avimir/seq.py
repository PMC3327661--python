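"""Nucleotide-string helpers shared across the pipeline.

All catalog sequences are held internally in RNA space (``ACGU``); genomes,
UTRs and raw reads are DNA (``ACGT``). Conversion happens at load time and is
idempotent.
"""

from __future__ import annotations

RNA_ALPHABET = frozenset("ACGU")
DNA_ALPHABET = frozenset("ACGT")

_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class AlphabetError(ValueError):
    """Raised when a sequence contains characters outside its alphabet."""


def to_rna(seq: str) -> str:
    """Normalize a nucleotide string to upper-case RNA (T -> U)."""
    s = seq.strip().upper().replace("T", "U")
    bad = set(s) - RNA_ALPHABET
    if bad:
        raise AlphabetError(f"non-RNA characters {sorted(bad)} in sequence {seq!r}")
    return s


def to_dna(seq: str) -> str:
    """Normalize a nucleotide string to upper-case DNA (U -> T)."""
    s = seq.strip().upper().replace("U", "T")
    bad = set(s) - DNA_ALPHABET
    if bad:
        raise AlphabetError(f"non-DNA characters {sorted(bad)} in sequence {seq!r}")
    return s


def revcomp_dna(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_DNA_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Hamming distance between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length sequences")
    return sum(x != y for x, y in zip(a, b))
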