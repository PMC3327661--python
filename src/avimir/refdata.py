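"""Reference-data model and I/O.

Holds the tiered mature/hairpin catalogs (chicken, then human, then
zebrafinch), contaminant sequence classes, the per-species genome panel, the
3'UTR set and gene/term annotations, plus validation and round-trippable
TSV/FASTA serialization.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional

from Bio import SeqIO

from .seq import RNA_ALPHABET, to_dna, to_rna

TIER_ORDER = ("chicken", "human", "zebrafinch")
CONTAMINANT_CLASSES = ("trna", "rrna", "snrna", "repeat", "mrna")
ARMS = ("five_prime", "three_prime", "unknown")

#: Species codes the artifact knows about (miRBase-style three-letter prefixes).
SPECIES_PANEL = ("gga", "apl", "cja", "tgu", "hsa", "mmu", "dre")

DEFAULT_LENGTH_BOUNDS = (18, 26)


@dataclass(frozen=True)
class MatureMiRNA:
    """One mature miRNA entry of a catalog tier (RNA space, 5'->3')."""

    name: str
    sequence: str
    hairpin_id: str
    arm: str = "unknown"
    is_star: bool = False
    annotated_species: frozenset = frozenset()


@dataclass(frozen=True)
class GenomeLocation:
    """0-based half-open genomic interval."""

    seqname: str
    start: int
    end: int
    strand: str = "+"


@dataclass
class Hairpin:
    """A pre-miRNA stem-loop with named arm intervals (0-based half-open).

    ``arm_intervals`` may register arms whose sequence is *not* a catalog
    mature (prospective star arms); the star-inference stage relies on these.
    """

    id: str
    species: str
    sequence: str
    location: Optional[GenomeLocation] = None
    arm_intervals: dict = field(default_factory=dict)

    def arm_slice(self, arm_name: str) -> str:
        start, end = self.arm_intervals[arm_name]
        return self.sequence[start:end]


@dataclass
class Catalog:
    """One tier of the reference: matures plus their hairpins."""

    matures: dict = field(default_factory=dict)   # name -> MatureMiRNA
    hairpins: dict = field(default_factory=dict)  # id -> Hairpin
    length_bounds: tuple = DEFAULT_LENGTH_BOUNDS

    def sequence_index(self) -> dict:
        """Map mature sequence -> sorted list of names carrying it."""
        idx: dict = {}
        for name in sorted(self.matures):
            idx.setdefault(self.matures[name].sequence, []).append(name)
        return idx


@dataclass
class UTR:
    transcript_id: str
    gene_id: str
    sequence: str  # DNA


@dataclass
class ReferenceSet:
    """All reference inputs needed by the annotation/quantification pipeline."""

    tiers: dict = field(default_factory=dict)          # tier name -> Catalog
    contaminants: dict = field(default_factory=dict)   # class -> {seq id: DNA}
    genome_panel: dict = field(default_factory=dict)   # species -> {contig: DNA}
    utrs: dict = field(default_factory=dict)           # transcript -> UTR
    terms: dict = field(default_factory=dict)          # term id -> frozenset of genes
    species_panel: tuple = SPECIES_PANEL

    def fingerprint(self) -> str:
        """Stable content hash used to guard against mixing reference sets."""
        h = hashlib.sha256()
        for tier in sorted(self.tiers):
            cat = self.tiers[tier]
            for name in sorted(cat.matures):
                m = cat.matures[name]
                h.update(f"{tier}|{name}|{m.sequence}|{m.hairpin_id}".encode())
            for hid in sorted(cat.hairpins):
                h.update(f"{tier}|{hid}|{cat.hairpins[hid].sequence}".encode())
        for cls in sorted(self.contaminants):
            for sid in sorted(self.contaminants[cls]):
                h.update(f"{cls}|{sid}|{self.contaminants[cls][sid]}".encode())
        for sp in sorted(self.genome_panel):
            for contig in sorted(self.genome_panel[sp]):
                h.update(f"{sp}|{contig}|{self.genome_panel[sp][contig]}".encode())
        return h.hexdigest()


# ---------------------------------------------------------------------------
# catalog I/O
# ---------------------------------------------------------------------------

SIDECAR_COLUMNS = (
    "record_type", "name", "hairpin_id", "arm", "is_star",
    "annotated_species", "arm_start", "arm_end",
)


def load_catalog(
    mature_fasta,
    sidecar_tsv,
    hairpin_fasta,
    species: str = "gga",
    length_bounds: tuple = DEFAULT_LENGTH_BOUNDS,
) -> Catalog:
    """Load one catalog tier from a mature FASTA, a hairpin FASTA and a TSV sidecar.

    The sidecar carries per-mature metadata (hairpin_id, arm, is_star,
    annotated_species, arm interval) plus optional ``arm`` rows registering
    non-catalog arm intervals on hairpins. U/T is normalized to U on load.

    Raises
    ------
    ValueError
        On duplicate mature names, on a mature that is not a slice of its
        hairpin, or on out-of-bounds sequence lengths.
    """
    matures_raw: dict = {}
    for rec in SeqIO.parse(str(mature_fasta), "fasta"):
        if rec.id in matures_raw:
            raise ValueError(f"duplicate mature name {rec.id!r} in {mature_fasta}")
        matures_raw[rec.id] = to_rna(str(rec.seq))

    hairpins: dict = {}
    for rec in SeqIO.parse(str(hairpin_fasta), "fasta"):
        if rec.id in hairpins:
            raise ValueError(f"duplicate hairpin id {rec.id!r} in {hairpin_fasta}")
        hairpins[rec.id] = Hairpin(id=rec.id, species=species, sequence=to_rna(str(rec.seq)))

    matures: dict = {}
    with open(sidecar_tsv, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            hid = row["hairpin_id"]
            if hid not in hairpins:
                raise ValueError(f"sidecar references unknown hairpin {hid!r}")
            hp = hairpins[hid]
            if row.get("record_type", "mature") == "arm":
                hp.arm_intervals[row["name"]] = (int(row["arm_start"]), int(row["arm_end"]))
                continue
            name = row["name"]
            if name not in matures_raw:
                raise ValueError(f"sidecar row for unknown mature {name!r}")
            seq = matures_raw[name]
            lo, hi = length_bounds
            if not lo <= len(seq) <= hi:
                raise ValueError(
                    f"mature {name!r} length {len(seq)} outside bounds [{lo}, {hi}]"
                )
            if row.get("arm_start"):
                start, end = int(row["arm_start"]), int(row["arm_end"])
            else:
                pos = hp.sequence.find(seq)
                if pos < 0:
                    raise ValueError(f"mature {name!r} is not a slice of hairpin {hid!r}")
                start, end = pos, pos + len(seq)
            if hp.sequence[start:end] != seq:
                raise ValueError(f"mature {name!r} is not a slice of hairpin {hid!r}")
            hp.arm_intervals[name] = (start, end)
            species_set = frozenset(
                s for s in row.get("annotated_species", "").split(",") if s
            )
            matures[name] = MatureMiRNA(
                name=name,
                sequence=seq,
                hairpin_id=hid,
                arm=row.get("arm", "unknown") or "unknown",
                is_star=row.get("is_star", "false").strip().lower() in ("1", "true", "yes"),
                annotated_species=species_set,
            )

    missing = set(matures_raw) - set(matures)
    if missing:
        raise ValueError(f"matures without sidecar rows: {sorted(missing)}")
    return Catalog(matures=matures, hairpins=hairpins, length_bounds=length_bounds)


def _write_fasta(path: Path, records: Iterable) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def write_catalog(catalog: Catalog, mature_fasta, sidecar_tsv, hairpin_fasta) -> None:
    """Serialize a catalog tier (inverse of :func:`load_catalog`)."""
    _write_fasta(Path(mature_fasta),
                 ((n, catalog.matures[n].sequence) for n in sorted(catalog.matures)))
    _write_fasta(Path(hairpin_fasta),
                 ((h, catalog.hairpins[h].sequence) for h in sorted(catalog.hairpins)))
    with open(sidecar_tsv, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(SIDECAR_COLUMNS)
        for name in sorted(catalog.matures):
            m = catalog.matures[name]
            start, end = catalog.hairpins[m.hairpin_id].arm_intervals[name]
            w.writerow([
                "mature", name, m.hairpin_id, m.arm, str(m.is_star).lower(),
                ",".join(sorted(m.annotated_species)), start, end,
            ])
        mature_names = set(catalog.matures)
        for hid in sorted(catalog.hairpins):
            hp = catalog.hairpins[hid]
            for arm_name in sorted(hp.arm_intervals):
                if arm_name in mature_names:
                    continue
                start, end = hp.arm_intervals[arm_name]
                w.writerow(["arm", arm_name, hid, "unknown", "false", "", start, end])


# ---------------------------------------------------------------------------
# reference-set I/O
# ---------------------------------------------------------------------------

def write_reference_set(rs: ReferenceSet, outdir) -> None:
    """Write a ReferenceSet as plain FASTA/TSV/JSON under ``outdir``."""
    out = Path(outdir)
    (out / "tiers").mkdir(parents=True, exist_ok=True)
    (out / "contaminants").mkdir(exist_ok=True)
    (out / "genomes").mkdir(exist_ok=True)
    tier_species = {}
    for tier, cat in rs.tiers.items():
        species = {hp.species for hp in cat.hairpins.values()} or {"gga"}
        tier_species[tier] = sorted(species)[0]
        write_catalog(
            cat,
            out / "tiers" / f"{tier}.matures.fa",
            out / "tiers" / f"{tier}.sidecar.tsv",
            out / "tiers" / f"{tier}.hairpins.fa",
        )
    for cls, seqs in rs.contaminants.items():
        _write_fasta(out / "contaminants" / f"{cls}.fa",
                     ((sid, seqs[sid]) for sid in sorted(seqs)))
    for sp, contigs in rs.genome_panel.items():
        _write_fasta(out / "genomes" / f"{sp}.fa",
                     ((c, contigs[c]) for c in sorted(contigs)))
    _write_fasta(out / "utrs.fa",
                 ((f"{u.transcript_id}|{u.gene_id}", u.sequence)
                  for u in (rs.utrs[t] for t in sorted(rs.utrs))))
    with open(out / "terms.tsv", "w") as fh:
        fh.write("term_id\tgene_id\n")
        for term in sorted(rs.terms):
            for gene in sorted(rs.terms[term]):
                fh.write(f"{term}\t{gene}\n")
    manifest = {
        "tiers": list(rs.tiers),
        "tier_species": tier_species,
        "contaminant_classes": sorted(rs.contaminants),
        "genome_species": sorted(rs.genome_panel),
        "species_panel": list(rs.species_panel),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def load_reference_set(indir) -> ReferenceSet:
    """Load a ReferenceSet written by :func:`write_reference_set`."""
    src = Path(indir)
    manifest = json.loads((src / "manifest.json").read_text())
    tiers = {}
    for tier in manifest["tiers"]:
        tiers[tier] = load_catalog(
            src / "tiers" / f"{tier}.matures.fa",
            src / "tiers" / f"{tier}.sidecar.tsv",
            src / "tiers" / f"{tier}.hairpins.fa",
            species=manifest["tier_species"][tier],
        )
    contaminants = {}
    for cls in manifest["contaminant_classes"]:
        contaminants[cls] = {
            rec.id: to_dna(str(rec.seq))
            for rec in SeqIO.parse(str(src / "contaminants" / f"{cls}.fa"), "fasta")
        }
    genome_panel = {}
    for sp in manifest["genome_species"]:
        genome_panel[sp] = {
            rec.id: to_dna(str(rec.seq))
            for rec in SeqIO.parse(str(src / "genomes" / f"{sp}.fa"), "fasta")
        }
    utrs = {}
    for rec in SeqIO.parse(str(src / "utrs.fa"), "fasta"):
        tx, _, gene = rec.id.partition("|")
        utrs[tx] = UTR(transcript_id=tx, gene_id=gene, sequence=to_dna(str(rec.seq)))
    terms: dict = {}
    with open(src / "terms.tsv") as fh:
        next(fh)
        for line in fh:
            term, gene = line.rstrip("\n").split("\t")
            terms.setdefault(term, set()).add(gene)
    terms = {t: frozenset(g) for t, g in terms.items()}
    return ReferenceSet(
        tiers=tiers,
        contaminants=contaminants,
        genome_panel=genome_panel,
        utrs=utrs,
        terms=terms,
        species_panel=tuple(manifest["species_panel"]),
    )


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_reference_set(rs: ReferenceSet) -> list:
    """Check every ReferenceSet invariant; return a list of violation strings.

    An empty report means the reference set is consistent.
    """
    report = []
    seen: dict = {}
    for tier, cat in rs.tiers.items():
        lo, hi = cat.length_bounds
        for name, m in cat.matures.items():
            if name in seen:
                report.append(
                    f"mature {name!r} present in tiers {seen[name]!r} and {tier!r}"
                )
            else:
                seen[name] = tier
            if set(m.sequence) - RNA_ALPHABET:
                report.append(f"mature {name!r} has non-RNA characters")
            if not lo <= len(m.sequence) <= hi:
                report.append(
                    f"mature {name!r} length {len(m.sequence)} outside [{lo}, {hi}]"
                )
            if m.hairpin_id not in cat.hairpins:
                report.append(f"mature {name!r} references missing hairpin {m.hairpin_id!r}")
                continue
            hp = cat.hairpins[m.hairpin_id]
            itv = hp.arm_intervals.get(name)
            if itv is None:
                report.append(f"mature {name!r} has no arm interval on {m.hairpin_id!r}")
            elif hp.sequence[itv[0]:itv[1]] != m.sequence:
                report.append(f"mature {name!r} is not a slice of hairpin {m.hairpin_id!r}")
            if m.arm not in ARMS:
                report.append(f"mature {name!r} has unknown arm {m.arm!r}")
            for sp in m.annotated_species:
                if sp not in rs.species_panel:
                    report.append(f"mature {name!r} annotated in unknown species {sp!r}")
        for hid, hp in cat.hairpins.items():
            n = len(hp.sequence)
            intervals = sorted(hp.arm_intervals.items(), key=lambda kv: kv[1])
            for arm_name, (start, end) in intervals:
                if not (0 <= start < end <= n):
                    report.append(
                        f"arm {arm_name!r} interval [{start}, {end}) outside hairpin "
                        f"{hid!r} of length {n}"
                    )
            for (a, (s1, e1)), (b, (s2, e2)) in zip(intervals, intervals[1:]):
                if s2 < e1:
                    report.append(f"arm intervals {a!r} and {b!r} overlap on hairpin {hid!r}")
            if hp.species not in rs.species_panel:
                report.append(f"hairpin {hid!r} has unknown species {hp.species!r}")
    return report


# ---------------------------------------------------------------------------
# packaged avian-candidate fixture
# ---------------------------------------------------------------------------

# Mature sequences of the six avian-lineage candidate miRNAs (miRBase v16
# chicken entries plus their star strands), keyed by miRBase-style names.
_CAND_LOOP = "GUUUCUGAAUUGUUG"
_CAND_FILL = "ACUGGCAUCAAGGAACGGUAAG"

AVIAN_CANDIDATES = (
    # name, sequence, hairpin_id, arm, is_star, annotated species
    ("gga-miR-1451", "UCGCACAGGAGCAAGUUACCGC", "gga-mir-1451", "five_prime", False, ("gga", "tgu")),
    ("gga-miR-1559", "UUCGAUGCUUGUAUGCUACUCC", "gga-mir-1559", "five_prime", False, ("gga",)),
    ("gga-miR-2131", "AUGCAGAAGUGCACGGAAACAGC", "gga-mir-2131", "five_prime", False, ("gga",)),
    ("gga-miR-2131*", "CUGUUACUGUUCUUCUGAUG", "gga-mir-2131", "three_prime", True, ("gga",)),
    ("gga-miR-2954", "CAUCCCCAUUCCACUCCUAGCA", "gga-mir-2954-1", "five_prime", False, ("gga", "tgu")),
    ("gga-miR-2954*", "GCUGAGAGGGCUUGGGGAGAGGA", "gga-mir-2954-2", "three_prime", True, ("gga",)),
)


def bundled_avian_candidates() -> Catalog:
    """The packaged avian-specific candidate fixture: 6 matures on 5 hairpins.

    Hairpins are synthetic stem-loops whose arm slices reproduce the mature
    sequences exactly; the two miR-2954 strands sit on distinct hairpin loci.
    """
    by_hairpin: dict = {}
    for name, seq, hid, arm, _star, _sp in AVIAN_CANDIDATES:
        by_hairpin.setdefault(hid, {})[arm] = (name, seq)
    hairpins = {}
    for hid, arms in by_hairpin.items():
        five = arms.get("five_prime", (None, _CAND_FILL))
        three = arms.get("three_prime", (None, _CAND_FILL))
        sequence = five[1] + _CAND_LOOP + three[1]
        intervals = {}
        if five[0]:
            intervals[five[0]] = (0, len(five[1]))
        if three[0]:
            start = len(five[1]) + len(_CAND_LOOP)
            intervals[three[0]] = (start, start + len(three[1]))
        hairpins[hid] = Hairpin(
            id=hid, species="gga", sequence=sequence, arm_intervals=intervals
        )
    matures = {
        name: MatureMiRNA(
            name=name, sequence=seq, hairpin_id=hid, arm=arm,
            is_star=star, annotated_species=frozenset(sp),
        )
        for name, seq, hid, arm, star, sp in AVIAN_CANDIDATES
    }
    return Catalog(matures=matures, hairpins=hairpins)
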