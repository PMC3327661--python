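"""Avian-lineage screen: candidate compilation and cross-genome presence calls."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Set, Tuple

from Bio import Align

from .refdata import Hairpin, MatureMiRNA, ReferenceSet
from .seq import revcomp_dna, to_dna

DEFAULT_IDENTITY_MIN = 0.9
DEFAULT_COVERAGE_MIN = 0.8

AVIAN_ANNOTATION_CODES = frozenset({"gga", "tgu"})


@dataclass
class ConservationCall:
    hairpin_id: str
    species: str
    present: bool
    best_identity: float
    best_coverage: float


@dataclass
class LineageVerdict:
    hairpin_id: str
    avian_specific: bool
    calls: Dict[str, ConservationCall] = field(default_factory=dict)


def compile_candidates(rs: ReferenceSet, detected: Set[str]) -> List[MatureMiRNA]:
    """Detected matures annotated only in avian species (gga and/or tgu)."""
    out = []
    for tier in rs.tiers:
        cat = rs.tiers[tier]
        for name in sorted(cat.matures):
            m = cat.matures[name]
            if not m.annotated_species:
                continue
            if not m.annotated_species <= AVIAN_ANNOTATION_CODES:
                continue
            if name not in detected:
                continue
            out.append(m)
    return out


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


def _alignment_stats(alignment, query: str, target: str) -> Tuple[float, float]:
    """(identity over aligned query span, query span / query length)."""
    blocks = alignment.aligned
    if len(blocks[0]) == 0:
        return 0.0, 0.0
    matches = 0
    for (ts, te), (qs, qe) in zip(blocks[0], blocks[1]):
        matches += sum(target[ts + i] == query[qs + i] for i in range(te - ts))
    q_start = blocks[1][0][0]
    q_end = blocks[1][-1][1]
    span = q_end - q_start
    return matches / span, span / len(query)


def search_presence(
    hairpin: Hairpin,
    genome: Dict[str, str],
    identity_min: float = DEFAULT_IDENTITY_MIN,
    coverage_min: float = DEFAULT_COVERAGE_MIN,
) -> ConservationCall:
    """Best local alignment of the hairpin against a genome, both strands.

    Present iff the best-scoring alignment reaches ``identity_min`` over its
    aligned hairpin span and covers at least ``coverage_min`` of the hairpin.
    """
    if not genome:
        raise ValueError("cannot screen an empty genome")
    if not (0 < identity_min <= 1 and 0 < coverage_min <= 1):
        raise ValueError("identity_min and coverage_min must be in (0, 1]")
    query = to_dna(hairpin.sequence)
    aligner = _aligner()
    best = (-1.0, 0.0, 0.0)  # score, identity, coverage
    for contig in sorted(genome):
        target = genome[contig]
        for strand_seq in (query, revcomp_dna(query)):
            score = aligner.score(target, strand_seq)
            if score <= best[0]:
                continue
            alignment = aligner.align(target, strand_seq)[0]
            identity, coverage = _alignment_stats(alignment, strand_seq, target)
            best = (score, identity, coverage)
    _, identity, coverage = best
    return ConservationCall(
        hairpin_id=hairpin.id,
        species="",
        present=identity >= identity_min and coverage >= coverage_min,
        best_identity=identity,
        best_coverage=coverage,
    )


def lineage_verdicts(
    hairpins: Iterable[Hairpin],
    genome_panel: Dict[str, Dict[str, str]],
    avian_species: Iterable[str],
    nonavian_species: Iterable[str],
    identity_min: float = DEFAULT_IDENTITY_MIN,
    coverage_min: float = DEFAULT_COVERAGE_MIN,
) -> List[LineageVerdict]:
    """Presence screen across the genome panel plus the avian-specific verdict.

    avian_specific holds iff the hairpin is present in every avian panel
    genome and absent from every non-avian one.
    """
    avian = list(avian_species)
    nonavian = list(nonavian_species)
    listed = set(avian) | set(nonavian)
    for sp in genome_panel:
        if sp not in listed:
            raise ValueError(f"panel species {sp!r} is in neither lineage list")
    verdicts = []
    for hp in hairpins:
        calls: Dict[str, ConservationCall] = {}
        for sp in avian + nonavian:
            call = search_presence(
                hp, genome_panel[sp],
                identity_min=identity_min, coverage_min=coverage_min,
            )
            call.species = sp
            calls[sp] = call
        avian_specific = (
            all(calls[sp].present for sp in avian)
            and not any(calls[sp].present for sp in nonavian)
        )
        verdicts.append(LineageVerdict(
            hairpin_id=hp.id, avian_specific=avian_specific, calls=calls,
        ))
    return verdicts


def write_verdicts(verdicts: Iterable[LineageVerdict], calls_path, summary_path) -> None:
    with open(calls_path, "w") as fh:
        fh.write("hairpin\tspecies\tpresent\tidentity\tcoverage\n")
        for v in verdicts:
            for sp in sorted(v.calls):
                c = v.calls[sp]
                fh.write(
                    f"{v.hairpin_id}\t{sp}\t{str(c.present).lower()}\t"
                    f"{c.best_identity:.4f}\t{c.best_coverage:.4f}\n"
                )
    with open(summary_path, "w") as fh:
        fh.write("hairpin\tavian_specific\n")
        for v in verdicts:
            fh.write(f"{v.hairpin_id}\t{str(v.avian_specific).lower()}\n")
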