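"""FASTQ preprocessing: adapter trimming, size selection, read collapsing.

Raw reads are ``insert + 3' adapter (+ tail)``; the insert 5' of the first
exact adapter-prefix occurrence is kept, size-selected to the 20-40 nt window
and collapsed to unique inserts with counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, List, Optional

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .seq import to_dna, to_rna

DEFAULT_MIN_OVERLAP = 8
DEFAULT_LENGTH_WINDOW = (20, 40)


@dataclass(frozen=True)
class RawRead:
    id: str
    sequence: str  # DNA
    quality: Optional[str] = None

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"read {self.id!r} has empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(f"read {self.id!r} quality/sequence length mismatch")


@dataclass(frozen=True)
class CollapsedRead:
    insert: str  # RNA
    count: int

    def __post_init__(self):
        if self.count < 1:
            raise ValueError("collapsed read count must be >= 1")


@dataclass
class Library:
    """One collapsed small-RNA library tagged with species and stage."""

    id: str
    species: str
    stage: str
    reads: List[CollapsedRead] = field(default_factory=list)
    n_raw: int = 0
    n_after_filters: int = 0


def trim_adapter(sequence: str, adapter: str, min_overlap: int = DEFAULT_MIN_OVERLAP):
    """Return the insert 5' of the first adapter occurrence, or None to discard.

    A match is an exact occurrence of an adapter *prefix* of length >=
    ``min_overlap`` (or of the full adapter when less of the read remains).
    Reads with no detectable adapter, or with the adapter at position 0
    (empty insert), are discarded.
    """
    if len(adapter) < min_overlap:
        raise ValueError(
            f"adapter length {len(adapter)} shorter than min_overlap {min_overlap}"
        )
    seq = to_dna(sequence)
    adapter = to_dna(adapter)
    probe = adapter[:min_overlap]
    i = seq.find(probe)
    while i != -1:
        span = min(len(adapter), len(seq) - i)
        if seq[i:i + span] == adapter[:span]:
            return seq[:i] if i > 0 else None
        i = seq.find(probe, i + 1)
    return None


def filter_length(inserts: Iterable[str], min_len: int = DEFAULT_LENGTH_WINDOW[0],
                  max_len: int = DEFAULT_LENGTH_WINDOW[1]) -> List[str]:
    """Size selection: keep inserts with min_len <= length <= max_len."""
    if not 0 < min_len <= max_len:
        raise ValueError(f"invalid length window [{min_len}, {max_len}]")
    return [s for s in inserts if min_len <= len(s) <= max_len]


def collapse(inserts: Iterable[str]) -> List[CollapsedRead]:
    """Collapse inserts to unique records, ordered by descending count then sequence."""
    counts: dict = {}
    for s in inserts:
        counts[s] = counts.get(s, 0) + 1
    return [
        CollapsedRead(insert=s, count=c)
        for s, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def parse_fastq(path) -> Iterator[RawRead]:
    """Iterate a (4-line) FASTQ file as RawRead records."""
    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield RawRead(id=title.split()[0], sequence=seq.upper(), quality=qual)


def build_library(
    fastq_path,
    library_id: str,
    species: str,
    stage: str,
    adapter: str,
    min_len: int = DEFAULT_LENGTH_WINDOW[0],
    max_len: int = DEFAULT_LENGTH_WINDOW[1],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> Library:
    """Run trim -> size-select -> collapse over a FASTQ file.

    The result is independent of input read order; inserts are stored in RNA
    space. ``n_after_filters`` equals the sum of collapsed counts.
    """
    n_raw = 0
    survivors = []
    for read in parse_fastq(fastq_path):
        n_raw += 1
        insert = trim_adapter(read.sequence, adapter, min_overlap=min_overlap)
        if insert is not None and min_len <= len(insert) <= max_len:
            survivors.append(to_rna(insert))
    collapsed = collapse(survivors)
    return Library(
        id=library_id,
        species=species,
        stage=stage,
        reads=collapsed,
        n_raw=n_raw,
        n_after_filters=len(survivors),
    )


def write_collapsed_fasta(library: Library, fasta_path, tsv_path=None) -> None:
    """Write collapsed reads as ``>seq{i}_x{count}`` FASTA plus an optional TSV mirror."""
    with open(fasta_path, "w") as fh:
        for i, cr in enumerate(library.reads, start=1):
            fh.write(f">seq{i}_x{cr.count}\n{cr.insert}\n")
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            fh.write("insert\tcount\n")
            for cr in library.reads:
                fh.write(f"{cr.insert}\t{cr.count}\n")
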