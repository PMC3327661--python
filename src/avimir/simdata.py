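"""Synthetic reference sets and FASTQ libraries with planted ground truth.

Emulates the study design: 6 libraries (3 species x 2 stages) of adapter-
ligated 20-40 nt inserts dominated by known miRNAs, with planted star
strands, exact and seed-preserving-mismatch orthologs, genome-gap orthologs,
contaminant classes, avian-specific hairpins across a genome panel, and
programmed between-library fold changes. Every planted sequence is
rejection-sampled against the annotation cascade's earlier stages so that at
zero error rate truth recovery is exact for any seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

from .annotate import CATEGORIES, annotate_read, match_seed_preserving
from .preprocess import trim_adapter
from .refdata import (
    Catalog,
    Hairpin,
    MatureMiRNA,
    ReferenceSet,
    UTR,
    bundled_avian_candidates,
    validate_reference_set,
    write_reference_set,
)
from .seq import hamming, revcomp_dna, to_dna, to_rna

DEFAULT_ADAPTER = "TCGTATGCCGTCTTCTGCTTG"

CATEGORY_FRACTION_DEFAULTS = {
    "known_mirna": 0.56,
    "star_mirna": 0.01,
    "ortholog_exact": 0.11,
    "ortholog_mismatch": 0.01,
    "genome_only": 0.04,
    "trna_rrna_snrna": 0.18,
    "repeat": 0.06,
    "degraded_mrna": 0.01,
    "unannotated": 0.02,
}

_DNA = np.frombuffer(b"ACGT", dtype="S1")

#: planted UTR transcript indices per candidate mature (deterministic design)
_UTR_PLANTS = {
    "gga-miR-1451": (6, 7, 8),
    "gga-miR-1559": (9,),
    "gga-miR-2131": (0, 1, 2, 3, 4, 5),
    "gga-miR-2131*": (1, 3),
    "gga-miR-2954": (2, 3, 4),
    "gga-miR-2954*": (5, 7, 9),
}


@dataclass
class LibrarySpec:
    id: str
    species: str
    stage: str
    depth: int


@dataclass
class SimulationSpec:
    libraries: List[LibrarySpec] = field(default_factory=list)
    adapter: str = DEFAULT_ADAPTER
    read_length: int = 50
    error_rate: float = 0.0
    mature_length: int = 22
    category_fractions: Dict[str, float] = field(
        default_factory=lambda: dict(CATEGORY_FRACTION_DEFAULTS)
    )
    n_known: int = 24
    n_star: int = 4
    n_ortholog_human: int = 6
    n_ortholog_zebrafinch: int = 2
    n_mismatch_variants: int = 3
    n_genome_only: int = 8
    n_unannotated: int = 6
    contaminant_refs: Dict[str, int] = field(
        default_factory=lambda: {"trna": 3, "rrna": 2, "snrna": 2, "repeat": 3, "mrna": 3}
    )
    contaminant_inserts: Dict[str, int] = field(
        default_factory=lambda: {"trna_rrna_snrna": 6, "repeat": 4, "degraded_mrna": 3}
    )
    candidate_weight: float = 3.0
    fold_log2: float = 2.0  # planted |log2 FC| (4-fold)
    n_utrs: int = 20


def default_spec(depth: int = 100_000) -> SimulationSpec:
    """The study-shaped default: 3 species x 2 stages at the given depth."""
    libraries = [
        LibrarySpec(id=f"{sp}-{stage}", species=sp, stage=stage, depth=depth)
        for sp in ("gga", "apl", "cja")
        for stage in ("HH20", "HH25")
    ]
    return SimulationSpec(libraries=libraries)


def validate_spec(spec: SimulationSpec) -> None:
    total = sum(spec.category_fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"category fractions sum to {total}, expected 1")
    if any(f < 0 for f in spec.category_fractions.values()):
        raise ValueError("category fractions must be in [0, 1]")
    if set(spec.category_fractions) != set(CATEGORIES):
        raise ValueError("category fractions must cover exactly the cascade categories")
    if not 0 <= spec.error_rate < 1:
        raise ValueError("error rate must be in [0, 1)")
    if len(spec.adapter) < 8:
        raise ValueError("adapter must be at least 8 nt")
    if not spec.libraries:
        raise ValueError("at least one library must be specified")


def spec_to_yaml(spec: SimulationSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(spec), fh, sort_keys=True)


def spec_from_yaml(path) -> SimulationSpec:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    data["libraries"] = [LibrarySpec(**lib) for lib in data.get("libraries", [])]
    return SimulationSpec(**data)


@dataclass
class TruthTable:
    """Planted composition plus realized per-library counts."""

    category_fractions: Dict[str, float] = field(default_factory=dict)
    insert_truth: Dict[str, Tuple[str, Optional[str]]] = field(default_factory=dict)
    items: List[Tuple[str, str, Optional[str]]] = field(default_factory=list)
    composition: Dict[str, np.ndarray] = field(default_factory=dict)
    counts: Dict[str, Dict[str, int]] = field(default_factory=dict)
    category_counts: Dict[str, Dict[str, int]] = field(default_factory=dict)
    mirna_counts: Dict[str, Dict[str, int]] = field(default_factory=dict)
    planted: Dict[str, object] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "category_fractions": self.category_fractions,
            "insert_truth": {k: list(v) for k, v in self.insert_truth.items()},
            "counts": self.counts,
            "category_counts": self.category_counts,
            "mirna_counts": self.mirna_counts,
            "planted": self.planted,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# random-sequence helpers
# ---------------------------------------------------------------------------

def _rand_dna(rng, n: int) -> str:
    return _DNA[rng.integers(0, 4, n)].tobytes().decode()


def _rand_rna(rng, n: int) -> str:
    return to_rna(_rand_dna(rng, n))


class _Planter:
    """Rejection-sampling helpers with visibility into what is planted so far."""

    def __init__(self, rng, spec: SimulationSpec):
        self.rng = rng
        self.spec = spec
        self.mature_seqs: Dict[str, str] = {}  # RNA -> name (all tiers)

    def insert_ok(self, rna: str) -> bool:
        """Adapter-safety: trimming insert+adapter must return the insert."""
        dna = to_dna(rna)
        return trim_adapter(dna + to_dna(self.spec.adapter), self.spec.adapter) == dna

    def clashes_catalog(self, rna: str, ignore: Optional[str] = None) -> bool:
        """True if rna is an exact catalog mature or within Hamming 2 of one."""
        for seq, name in self.mature_seqs.items():
            if name == ignore:
                continue
            if seq == rna:
                return True
            if len(seq) == len(rna) and hamming(seq, rna) <= 2:
                return True
        return False

    def register(self, rna: str, name: str) -> None:
        self.mature_seqs[rna] = name

    def fresh_mature(self, name: str, length: int) -> str:
        for _ in range(1000):
            rna = _rand_rna(self.rng, length)
            if self.insert_ok(rna) and not self.clashes_catalog(rna):
                self.register(rna, name)
                return rna
        raise RuntimeError("failed to draw a fresh mature sequence")


def _build_hairpin(planter: _Planter, hid: str, species: str, mature_name: str,
                   mature_seq: str, star_arm: Optional[str]) -> Hairpin:
    loop = _rand_rna(planter.rng, 14)
    if star_arm is None:
        opp = _rand_rna(planter.rng, len(mature_seq))
        intervals = {mature_name: (0, len(mature_seq))}
        seq = mature_seq + loop + opp
    else:
        intervals = {
            mature_name: (0, len(mature_seq)),
            mature_name + "-ukstar": (
                len(mature_seq) + len(loop),
                len(mature_seq) + len(loop) + len(star_arm),
            ),
        }
        seq = mature_seq + loop + star_arm
    return Hairpin(id=hid, species=species, sequence=seq, arm_intervals=intervals)


def make_reference_set(spec: SimulationSpec, seed: int) -> Tuple[ReferenceSet, TruthTable]:
    """Generate the full reference fixture and the truth-table stub.

    The chicken tier embeds the packaged avian-candidate fixture verbatim and
    a conserved control; candidate hairpins are planted in every avian panel
    genome and in no non-avian one. Same spec + seed => identical output.
    """
    validate_spec(spec)
    rng = np.random.default_rng([seed, 0])
    planter = _Planter(rng, spec)
    truth = TruthTable(category_fractions=dict(spec.category_fractions))
    L = spec.mature_length

    # --- chicken tier -----------------------------------------------------
    chicken = Catalog()
    candidates = bundled_avian_candidates()
    for name in sorted(candidates.matures):
        m = candidates.matures[name]
        if not planter.insert_ok(m.sequence):
            raise ValueError("adapter collides with a packaged candidate sequence")
        planter.register(m.sequence, name)
        chicken.matures[name] = m
    chicken.hairpins.update(candidates.hairpins)

    star_names: Dict[str, str] = {}  # star insert RNA -> star name
    for i in range(spec.n_known):
        name = f"gga-sim-mir-{i + 1:03d}"
        seq = planter.fresh_mature(name, L)
        hid = f"gga-sim-hp-{i + 1:03d}"
        star_arm = None
        if i < spec.n_star:
            star_arm = planter.fresh_mature(name + "-ukstar", L)
            star_names[star_arm] = name + "-ukstar"
        chicken.matures[name] = MatureMiRNA(
            name=name, sequence=seq, hairpin_id=hid, arm="five_prime",
            annotated_species=frozenset({"gga", "hsa"}),
        )
        chicken.hairpins[hid] = _build_hairpin(planter, hid, "gga", name, seq, star_arm)

    control_name = "gga-sim-mir-100"
    control_seq = planter.fresh_mature(control_name, L)
    chicken.matures[control_name] = MatureMiRNA(
        name=control_name, sequence=control_seq, hairpin_id="gga-sim-hp-100",
        arm="five_prime", annotated_species=frozenset({"gga", "hsa", "dre"}),
    )
    control_hairpin = _build_hairpin(
        planter, "gga-sim-hp-100", "gga", control_name, control_seq, None
    )
    chicken.hairpins["gga-sim-hp-100"] = control_hairpin

    # --- ortholog tiers ---------------------------------------------------
    human = Catalog()
    for i in range(spec.n_ortholog_human):
        name = f"hsa-sim-mir-{i + 1:03d}"
        seq = planter.fresh_mature(name, L)
        hid = f"hsa-sim-hp-{i + 1:03d}"
        human.matures[name] = MatureMiRNA(
            name=name, sequence=seq, hairpin_id=hid, arm="five_prime",
            annotated_species=frozenset({"hsa"}),
        )
        human.hairpins[hid] = _build_hairpin(planter, hid, "hsa", name, seq, None)

    zebrafinch = Catalog()
    for i in range(spec.n_ortholog_zebrafinch):
        name = f"tgu-sim-mir-{i + 1:03d}"
        seq = planter.fresh_mature(name, L)
        hid = f"tgu-sim-hp-{i + 1:03d}"
        # annotated in human as well so only the packaged fixture qualifies
        # as avian-only in the candidate screen
        zebrafinch.matures[name] = MatureMiRNA(
            name=name, sequence=seq, hairpin_id=hid, arm="five_prime",
            annotated_species=frozenset({"tgu", "hsa"}),
        )
        zebrafinch.hairpins[hid] = _build_hairpin(planter, hid, "tgu", name, seq, None)

    tiers = {"chicken": chicken, "human": human, "zebrafinch": zebrafinch}

    # --- seed-preserving mismatch variants of human matures ---------------
    variants: Dict[str, Tuple[str, Tuple[int, ...]]] = {}  # insert -> (name, positions)
    human_names = sorted(human.matures)
    for j in range(min(spec.n_mismatch_variants, len(human_names))):
        source = human.matures[human_names[j]]
        for _ in range(1000):
            n_mm = 1 + (j % 2)
            positions = sorted(
                int(p) for p in rng.choice(np.arange(10, L - 1), size=n_mm, replace=False)
            )
            var = list(source.sequence)
            for p in positions:
                choices = [b for b in "ACGU" if b != var[p - 1]]
                var[p - 1] = choices[int(rng.integers(0, 3))]
            var = "".join(var)
            if not planter.insert_ok(var):
                continue
            if planter.clashes_catalog(var, ignore=source.name):
                continue
            hits = match_seed_preserving(var, human)
            if [(h[0], h[1]) for h in hits] != [(source.name, tuple(positions))]:
                continue
            variants[var] = (source.name, tuple(positions))
            break
        else:
            raise RuntimeError("failed to plant a mismatch variant")

    # --- contaminant classes ---------------------------------------------
    contaminants: Dict[str, Dict[str, str]] = {}
    for cls in sorted(spec.contaminant_refs):
        contaminants[cls] = {
            f"{cls}-{i + 1}": _rand_dna(rng, 120)
            for i in range(spec.contaminant_refs[cls])
        }
    group_classes = {
        "trna_rrna_snrna": ("trna", "rrna", "snrna"),
        "repeat": ("repeat",),
        "degraded_mrna": ("mrna",),
    }
    hairpin_pool = [to_dna(hp.sequence) for hp in chicken.hairpins.values()]
    contaminant_items: Dict[str, str] = {}  # insert RNA -> category
    for category in ("trna_rrna_snrna", "repeat", "degraded_mrna"):
        refs = []
        for cls in group_classes[category]:
            refs.extend(sorted(contaminants[cls].values()))
        for _ in range(spec.contaminant_inserts[category]):
            for _try in range(1000):
                ref = refs[int(rng.integers(0, len(refs)))]
                length = int(rng.integers(20, 35))
                off = int(rng.integers(0, len(ref) - length + 1))
                rna = to_rna(ref[off:off + length])
                if rna in contaminant_items:
                    continue
                if not planter.insert_ok(rna):
                    continue
                if planter.clashes_catalog(rna):
                    continue
                if any(to_dna(rna) in hp for hp in hairpin_pool):
                    continue
                # precedence closed-loop check
                hit = None
                for cat2, classes in group_classes.items():
                    if any(to_dna(rna) in s for cls in classes
                           for s in contaminants[cls].values()):
                        hit = cat2
                        break
                if hit != category:
                    continue
                contaminant_items[rna] = category
                break
            else:
                raise RuntimeError(f"failed to plant a {category} insert")

    # --- genome-only inserts and genome panel -----------------------------
    genome_only: List[str] = []
    for _ in range(spec.n_genome_only):
        for _try in range(1000):
            rna = _rand_rna(rng, L)
            if not planter.insert_ok(rna) or planter.clashes_catalog(rna):
                continue
            if any(to_dna(rna) in hp for hp in hairpin_pool):
                continue
            if any(to_dna(rna) in s for cls in contaminants
                   for s in contaminants[cls].values()):
                continue
            genome_only.append(rna)
            break
        else:
            raise RuntimeError("failed to plant a genome-only insert")

    def _assemble(plants: List[str]) -> str:
        parts = [_rand_dna(rng, 300)]
        for p in plants:
            parts.append(p)
            parts.append(_rand_dna(rng, 120))
        return "".join(parts)

    candidate_hids = sorted(candidates.hairpins)
    candidate_dna = [to_dna(candidates.hairpins[h].sequence) for h in candidate_hids]
    control_dna = to_dna(control_hairpin.sequence)
    gga_plants = sorted(hairpin_pool) + [to_dna(r) for r in genome_only]
    genome_panel = {
        "gga": {"chr1": _assemble(gga_plants)},
        "apl": {"chr1": _assemble(candidate_dna + [control_dna])},
        "cja": {"chr1": _assemble(candidate_dna + [control_dna])},
        "hsa": {"chr1": _assemble(
            [to_dna(hp.sequence) for hp in human.hairpins.values()] + [control_dna]
        )},
        "dre": {"chr1": _assemble([control_dna])},
    }

    # --- unannotated inserts (drawn after the genome exists) ---------------
    gga_contigs = list(genome_panel["gga"].values())
    unannotated: List[str] = []
    for _ in range(spec.n_unannotated):
        for _try in range(1000):
            rna = _rand_rna(rng, L)
            dna = to_dna(rna)
            if not planter.insert_ok(rna) or planter.clashes_catalog(rna):
                continue
            if any(dna in c or revcomp_dna(dna) in c for c in gga_contigs):
                continue
            if any(dna in hp for hp in hairpin_pool):
                continue
            if any(dna in s for cls in contaminants
                   for s in contaminants[cls].values()):
                continue
            unannotated.append(rna)
            break
        else:
            raise RuntimeError("failed to plant an unannotated insert")

    # --- UTRs and term annotations ----------------------------------------
    seeds = {
        name: revcomp_dna(to_dna(candidates.matures[name].sequence[1:8]))
        for name in sorted(candidates.matures)
    }

    def _scrubbed(n: int) -> str:
        for _try in range(200):
            s = _rand_dna(rng, n)
            if not any(m in s for m in seeds.values()):
                return s
        raise RuntimeError("failed to draw a seed-free UTR segment")

    plant_by_tx: Dict[int, List[str]] = {}
    for name, idxs in _UTR_PLANTS.items():
        for i in idxs:
            plant_by_tx.setdefault(i, []).append(name)
    utrs: Dict[str, UTR] = {}
    for i in range(spec.n_utrs):
        tx, gene = f"tx{i + 1:03d}", f"gene{i + 1:03d}"
        for _try in range(100):
            parts = [_scrubbed(110)]
            for j, name in enumerate(sorted(plant_by_tx.get(i, []))):
                tail = "A" if (i + j) % 2 == 0 else "G"
                parts.append(seeds[name] + tail)
                parts.append(_scrubbed(30))
            parts.append(_scrubbed(70))
            seq = "".join(parts)
            counts = {name: seq.count(seeds[name]) for name in seeds}
            want = {name: sorted(plant_by_tx.get(i, [])).count(name) for name in seeds}
            if counts == want:
                utrs[tx] = UTR(transcript_id=tx, gene_id=gene, sequence=seq)
                break
        else:
            raise RuntimeError("failed to build a clean UTR")

    genes = [f"gene{i + 1:03d}" for i in range(spec.n_utrs)]
    terms = {
        "T:dev-signaling": frozenset(genes[0:6]),
        "T:metabolism": frozenset(genes[6:12]),
        "T:structure": frozenset(genes[12:]),
        "T:housekeeping": frozenset(genes[::2]),
    }

    rs = ReferenceSet(
        tiers=tiers,
        contaminants=contaminants,
        genome_panel=genome_panel,
        utrs=utrs,
        terms=terms,
    )
    problems = validate_reference_set(rs)
    if problems:
        raise RuntimeError(f"generated reference set is inconsistent: {problems}")

    # --- truth composition -------------------------------------------------
    known_names = sorted(n for n in chicken.matures)
    sim_names = [n for n in known_names if n.startswith("gga-sim-mir-")
                 and n != control_name]
    de_up = sim_names[0:2]
    de_down = sim_names[2:4]
    duck_high = sim_names[4:5]

    def base_weight(name: str) -> float:
        if name in candidates.matures:
            return spec.candidate_weight
        if name == control_name:
            return 2.0
        return 1.0

    items: List[Tuple[str, str, Optional[str]]] = []
    for name in known_names:
        items.append((chicken.matures[name].sequence, "known_mirna", name))
    for arm in sorted(star_names):
        items.append((arm, "star_mirna", star_names[arm]))
    for name in sorted(human.matures):
        items.append((human.matures[name].sequence, "ortholog_exact", name))
    for name in sorted(zebrafinch.matures):
        items.append((zebrafinch.matures[name].sequence, "ortholog_exact", name))
    for var in sorted(variants):
        items.append((var, "ortholog_mismatch", variants[var][0]))
    for rna in genome_only:
        items.append((rna, "genome_only", None))
    for rna in sorted(contaminant_items):
        items.append((rna, contaminant_items[rna], None))
    for rna in unannotated:
        items.append((rna, "unannotated", None))

    truth.items = items
    truth.insert_truth = {ins: (cat, name) for ins, cat, name in items}
    truth.planted = {
        "star_names": sorted(star_names.values()),
        "variants": {var: [variants[var][0], list(variants[var][1])]
                     for var in sorted(variants)},
        "avian_hairpins": candidate_hids,
        "control_hairpin": control_hairpin.id,
        "de_up": de_up,
        "de_down": de_down,
        "duck_high": duck_high,
        "fold_log2": spec.fold_log2,
        "candidate_matures": sorted(candidates.matures),
    }

    fracs = spec.category_fractions
    fold = 2.0 ** spec.fold_log2
    for lib in spec.libraries:
        weights = []
        for ins, cat, name in items:
            if cat == "known_mirna":
                w = base_weight(name)
                if name in de_up and lib.stage == "HH25":
                    w *= fold
                elif name in de_down and lib.stage == "HH20":
                    w *= fold
                elif name in duck_high and lib.species == "apl":
                    w *= fold
            else:
                w = 1.0
            weights.append(w)
        weights = np.asarray(weights, dtype=float)
        probs = np.zeros_like(weights)
        for cat in CATEGORIES:
            mask = np.array([c == cat for _, c, _ in items])
            if mask.any():
                probs[mask] = fracs[cat] * weights[mask] / weights[mask].sum()
        probs /= probs.sum()
        truth.composition[lib.id] = probs

    # --- final closed-loop verification ------------------------------------
    for ins, cat, name in items:
        rec = annotate_read(ins, rs)
        if rec.category != cat or (name is not None and rec.assigned_name != name):
            raise RuntimeError(
                f"planted insert {ins} resolved to {rec.category}/{rec.assigned_name}, "
                f"expected {cat}/{name}"
            )
    return rs, truth


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def simulate_libraries(
    spec: SimulationSpec,
    rs: ReferenceSet,
    truth: TruthTable,
    seed: int,
    out_dir,
) -> List[Path]:
    """Write one FASTQ per library and fill the truth table's realized counts.

    Reads are ``insert + adapter (+ random tail)`` padded/truncated to the
    configured read length, with uniform substitution errors at the spec's
    rate. Identical spec + seed produce byte-identical files.
    """
    validate_spec(spec)
    rng = np.random.default_rng([seed, 1])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    adapter = to_dna(spec.adapter)
    paths = []
    manifest_rows = []
    for lib in spec.libraries:
        if lib.depth < 1000:
            warnings.warn(
                f"library {lib.id!r} depth {lib.depth} < 1000: fractions will be "
                "unstable", stacklevel=2,
            )
        probs = truth.composition[lib.id]
        counts = rng.multinomial(lib.depth, probs)
        order = np.repeat(np.arange(len(truth.items)), counts)
        rng.shuffle(order)

        lib_counts: Dict[str, int] = {}
        cat_counts: Dict[str, int] = {c: 0 for c in CATEGORIES}
        mir_counts: Dict[str, int] = {}
        for idx, c in enumerate(counts):
            ins, cat, name = truth.items[idx]
            if c == 0:
                continue
            lib_counts[ins] = int(c)
            cat_counts[cat] += int(c)
            if name is not None:
                mir_counts[name] = mir_counts.get(name, 0) + int(c)
        truth.counts[lib.id] = lib_counts
        truth.category_counts[lib.id] = cat_counts
        truth.mirna_counts[lib.id] = mir_counts

        path = out / f"{lib.id}.fastq"
        with open(path, "w") as fh:
            for rid, idx in enumerate(order, start=1):
                ins = to_dna(truth.items[idx][0])
                read = ins + adapter
                if len(read) < spec.read_length:
                    read += _rand_dna(rng, spec.read_length - len(read))
                else:
                    read = read[:spec.read_length]
                if spec.error_rate > 0:
                    mask = rng.random(len(read)) < spec.error_rate
                    if mask.any():
                        arr = list(read)
                        for pos in np.flatnonzero(mask):
                            choices = [b for b in "ACGT" if b != arr[pos]]
                            arr[pos] = choices[int(rng.integers(0, 3))]
                        read = "".join(arr)
                fh.write(f"@{lib.id}_{rid}\n{read}\n+\n{'I' * len(read)}\n")
        paths.append(path)
        manifest_rows.append(
            f"{lib.id}\t{lib.species}\t{lib.stage}\t{path.name}\t{lib.depth}"
        )
    with open(out / "libraries.tsv", "w") as fh:
        fh.write("library\tspecies\tstage\tfastq\tdepth\n")
        for row in manifest_rows:
            fh.write(row + "\n")
    return paths


def simulate(spec: SimulationSpec, seed: int, out_dir) -> Tuple[ReferenceSet, TruthTable]:
    """Convenience end-to-end generator: reference set + FASTQs + truth JSON."""
    out = Path(out_dir)
    rs, truth = make_reference_set(spec, seed)
    write_reference_set(rs, out / "refset")
    simulate_libraries(spec, rs, truth, seed, out / "reads")
    truth.to_json(out / "truth.json")
    spec_to_yaml(spec, out / "spec.yaml")
    return rs, truth
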