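"""Annotation cascade: assign every collapsed read to exactly one category.

Cascade order (first hit wins): known chicken mature -> inferred star strand
-> exact ortholog (human tier, then zebrafinch) -> seed-preserving mismatch
ortholog -> chicken-genome hit -> contaminant classes -> unannotated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .preprocess import Library
from .refdata import Catalog, GenomeLocation, ReferenceSet
from .seq import revcomp_dna, to_dna, to_rna

logger = logging.getLogger(__name__)

MIRNA_CATEGORIES = ("known_mirna", "star_mirna", "ortholog_exact", "ortholog_mismatch")
CATEGORIES = MIRNA_CATEGORIES + (
    "genome_only", "repeat", "trna_rrna_snrna", "degraded_mrna", "unannotated",
)

#: seed positions on the mature strand, 1-based inclusive
SEED_SPAN = (2, 8)

#: contaminant category -> storage classes, in fixed precedence order
CONTAMINANT_PRECEDENCE = (
    ("trna_rrna_snrna", ("trna", "rrna", "snrna")),
    ("repeat", ("repeat",)),
    ("degraded_mrna", ("mrna",)),
)

STAR_SUFFIX = "-ukstar"


@dataclass
class AnnotationRecord:
    """Category assignment for one collapsed read."""

    insert: str
    count: int
    category: str
    assigned_name: Optional[str] = None
    tier: Optional[str] = None
    mismatch_positions: Tuple[int, ...] = ()
    tied_names: Tuple[str, ...] = ()


@dataclass
class AnnotationSummary:
    library_id: str
    total_reads: int
    fractions: Dict[str, float] = field(default_factory=dict)
    distinct: Dict[str, int] = field(default_factory=dict)
    mapped_reads: int = 0
    ref_fingerprint: str = ""


def match_exact(insert: str, catalog: Catalog) -> List[str]:
    """Names of catalog matures whose sequence equals the insert exactly."""
    return list(catalog.sequence_index().get(to_rna(insert), []))


def infer_star(insert: str, hairpins: Dict[str, object], annotated_names) -> Optional[Tuple[str, str]]:
    """Look for the insert inside the arm opposite an annotated mature arm.

    Returns ``(hairpin_id, "<mature>-ukstar")`` for the first (sorted) hairpin
    whose registered-but-unannotated opposite arm contains the insert as an
    exact substring, else None. Inserts overlapping only the loop never hit.
    """
    query = to_rna(insert)
    for hid in sorted(hairpins):
        hp = hairpins[hid]
        arm_names = sorted(hp.arm_intervals)
        for mature_name in arm_names:
            if mature_name not in annotated_names:
                continue
            for other in arm_names:
                if other == mature_name or other in annotated_names:
                    continue
                if query in hp.arm_slice(other):
                    return hid, mature_name + STAR_SUFFIX
    return None


def match_seed_preserving(insert: str, catalog: Catalog, max_mm: int = 2) -> List[Tuple[str, Tuple[int, ...]]]:
    """Equal-length Hamming hits with 1..max_mm mismatches, all outside the seed.

    Mismatch positions are 1-based on the mature reference and reported in
    ascending order; any mismatch inside positions 2-8 disqualifies the hit.
    """
    query = to_rna(insert)
    lo, hi = SEED_SPAN
    hits = []
    for name in sorted(catalog.matures):
        ref = catalog.matures[name].sequence
        if len(ref) != len(query):
            continue
        positions = []
        for i, (a, b) in enumerate(zip(ref, query), start=1):
            if a != b:
                positions.append(i)
                if len(positions) > max_mm:
                    break
        if not 1 <= len(positions) <= max_mm:
            continue
        if any(lo <= p <= hi for p in positions):
            continue
        hits.append((name, tuple(positions)))
    return hits


def map_genome(insert: str, genome: Dict[str, str]) -> List[GenomeLocation]:
    """All exact full-length occurrences of the insert in a genome, both strands."""
    query = to_dna(insert)
    rc = revcomp_dna(query)
    hits = []
    for contig in sorted(genome):
        seq = genome[contig]
        for probe, strand in ((query, "+"), (rc, "-")):
            start = seq.find(probe)
            while start != -1:
                hits.append(GenomeLocation(contig, start, start + len(probe), strand))
                start = seq.find(probe, start + 1)
    hits.sort(key=lambda loc: (loc.seqname, loc.start, loc.strand))
    return hits


def classify_contaminant(insert: str, contaminants: Dict[str, Dict[str, str]]) -> Optional[str]:
    """First contaminant category whose class sequences contain the insert.

    Precedence is fixed: trna_rrna_snrna -> repeat -> degraded_mrna; a match
    is an exact substring occurrence in any sequence of the class.
    """
    query = to_dna(insert)
    for category, classes in CONTAMINANT_PRECEDENCE:
        for cls in classes:
            for sid in sorted(contaminants.get(cls, {})):
                if query in contaminants[cls][sid]:
                    return category
    return None


def _pick(names: List[str]) -> Tuple[str, Tuple[str, ...]]:
    """Tie rule: assign the lexicographically first name, keep the rest on record."""
    names = sorted(names)
    if len(names) > 1:
        logger.debug("ambiguous assignment, tie between %s", names)
        return names[0], tuple(names)
    return names[0], ()


def annotate_read(
    insert: str,
    rs: ReferenceSet,
    genome_species: str = "gga",
    max_mm: int = 2,
) -> AnnotationRecord:
    """Run the cascade for a single insert (count left at 1)."""
    rec = AnnotationRecord(insert=insert, count=1, category="unannotated")

    chicken = rs.tiers.get("chicken", Catalog())
    names = match_exact(insert, chicken)
    if names:
        rec.category = "known_mirna"
        rec.tier = "chicken"
        rec.assigned_name, rec.tied_names = _pick(names)
        return rec

    annotated = set(chicken.matures)
    star = infer_star(insert, chicken.hairpins, annotated)
    if star is not None:
        rec.category = "star_mirna"
        rec.tier = "chicken"
        rec.assigned_name = star[1]
        return rec

    for tier in ("human", "zebrafinch"):
        cat = rs.tiers.get(tier)
        if cat is None:
            continue
        names = match_exact(insert, cat)
        if names:
            rec.category = "ortholog_exact"
            rec.tier = tier
            rec.assigned_name, rec.tied_names = _pick(names)
            return rec

    for tier in ("human", "zebrafinch"):
        cat = rs.tiers.get(tier)
        if cat is None:
            continue
        hits = match_seed_preserving(insert, cat, max_mm=max_mm)
        if hits:
            hits.sort(key=lambda h: (len(h[1]), h[0]))
            best = hits[0]
            rec.category = "ortholog_mismatch"
            rec.tier = tier
            rec.assigned_name = best[0]
            rec.mismatch_positions = best[1]
            if len(hits) > 1:
                rec.tied_names = tuple(sorted(h[0] for h in hits))
            return rec

    genome = rs.genome_panel.get(genome_species, {})
    if genome and map_genome(insert, genome):
        rec.category = "genome_only"
        return rec

    contaminant = classify_contaminant(insert, rs.contaminants)
    if contaminant is not None:
        rec.category = contaminant
        return rec

    return rec


def annotate_library(
    library: Library,
    rs: ReferenceSet,
    genome_species: str = "gga",
    max_mm: int = 2,
) -> Tuple[List[AnnotationRecord], AnnotationSummary]:
    """Annotate every collapsed read of a library and summarize by category.

    Each read receives exactly one category; summary fractions are weighted by
    collapsed counts and sum to one. The mapped-read denominator counts every
    category except ``unannotated``.
    """
    if not library.reads:
        raise ValueError(f"library {library.id!r} has no reads to annotate")
    records = []
    cat_counts = {c: 0 for c in CATEGORIES}
    distinct: Dict[str, set] = {c: set() for c in CATEGORIES}
    for cr in library.reads:
        rec = annotate_read(cr.insert, rs, genome_species=genome_species, max_mm=max_mm)
        rec.count = cr.count
        records.append(rec)
        cat_counts[rec.category] += cr.count
        distinct[rec.category].add(rec.assigned_name or rec.insert)
    total = sum(cat_counts.values())
    summary = AnnotationSummary(
        library_id=library.id,
        total_reads=total,
        fractions={c: cat_counts[c] / total for c in CATEGORIES},
        distinct={c: len(distinct[c]) for c in CATEGORIES},
        mapped_reads=total - cat_counts["unannotated"],
        ref_fingerprint=rs.fingerprint(),
    )
    return records, summary


def write_records(records: List[AnnotationRecord], path) -> None:
    """TSV export of annotation records."""
    with open(path, "w") as fh:
        fh.write("insert\tcount\tcategory\tassigned_name\ttier\tmismatch_positions\n")
        for r in records:
            mm = ",".join(str(p) for p in r.mismatch_positions)
            fh.write(
                f"{r.insert}\t{r.count}\t{r.category}\t{r.assigned_name or ''}\t"
                f"{r.tier or ''}\t{mm}\n"
            )
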