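"""Annotation cascade: stage operations, precedence and the brute-force oracle."""

import numpy as np
import pytest

from avimir.annotate import (
    CATEGORIES,
    annotate_library,
    annotate_read,
    classify_contaminant,
    infer_star,
    map_genome,
    match_exact,
    match_seed_preserving,
)
from avimir.preprocess import CollapsedRead, Library
from avimir.refdata import ReferenceSet, bundled_avian_candidates
from avimir.seq import revcomp_dna, to_dna, to_rna

CANDIDATES = bundled_avian_candidates()


# ---------------------------------------------------------------------------
# match_exact
# ---------------------------------------------------------------------------

def test_match_exact_hits_by_sequence():
    assert match_exact("CAUCCCCAUUCCACUCCUAGCA", CANDIDATES) == ["gga-miR-2954"]


def test_match_exact_single_substitution_misses():
    assert match_exact("CAUCCCCAUUCCACUCCUAGCU", CANDIDATES) == []


def test_match_exact_normalizes_dna_spelling():
    assert match_exact("CATCCCCATTCCACTCCTAGCA", CANDIDATES) == ["gga-miR-2954"]


# ---------------------------------------------------------------------------
# infer_star
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def star_hairpin(small_sim):
    _, rs, truth, _ = small_sim
    chicken = rs.tiers["chicken"]
    star_name = truth.planted["star_names"][0]
    mature = star_name[: -len("-ukstar")]
    hp = chicken.hairpins[chicken.matures[mature].hairpin_id]
    return chicken, hp, mature, star_name


def test_infer_star_finds_opposite_arm_slice(star_hairpin):
    chicken, hp, mature, star_name = star_hairpin
    insert = hp.arm_slice(star_name)
    hit = infer_star(insert, chicken.hairpins, set(chicken.matures))
    assert hit == (hp.id, star_name)


def test_infer_star_ignores_loop_only_insert(star_hairpin):
    chicken, hp, mature, star_name = star_hairpin
    m_end = hp.arm_intervals[mature][1]
    s_start = hp.arm_intervals[star_name][0]
    loop = hp.sequence[m_end:s_start]
    assert infer_star(loop, chicken.hairpins, set(chicken.matures)) is None


def test_infer_star_does_not_fire_on_the_mature_arm(star_hairpin):
    chicken, hp, mature, star_name = star_hairpin
    insert = hp.arm_slice(mature)
    assert infer_star(insert, chicken.hairpins, set(chicken.matures)) is None


# ---------------------------------------------------------------------------
# match_seed_preserving (with an exhaustive Hamming-scan oracle)
# ---------------------------------------------------------------------------

def oracle_seed_preserving(insert, catalog, max_mm=2):
    insert = to_rna(insert)
    hits = []
    for name in sorted(catalog.matures):
        ref = catalog.matures[name].sequence
        if len(ref) != len(insert):
            continue
        mm = [i for i in range(1, len(ref) + 1) if ref[i - 1] != insert[i - 1]]
        if 1 <= len(mm) <= max_mm and not any(2 <= p <= 8 for p in mm):
            hits.append((name, tuple(mm)))
    return hits


def _mutate(seq, pos_1based):
    alt = {"A": "C", "C": "G", "G": "U", "U": "A"}
    chars = list(seq)
    chars[pos_1based - 1] = alt[chars[pos_1based - 1]]
    return "".join(chars)


def test_seed_preserving_outside_seed_hit():
    query = _mutate("UUCGAUGCUUGUAUGCUACUCC", 15)
    hits = match_seed_preserving(query, CANDIDATES)
    assert hits == [("gga-miR-1559", (15,))]
    assert hits == oracle_seed_preserving(query, CANDIDATES)


def test_seed_preserving_inside_seed_rejected():
    query = _mutate("UUCGAUGCUUGUAUGCUACUCC", 3)
    assert match_seed_preserving(query, CANDIDATES) == []
    assert oracle_seed_preserving(query, CANDIDATES) == []


def test_seed_preserving_three_mismatches_rejected():
    query = "UUCGAUGCUUGUAUGCUACUCC"
    for pos in (10, 15, 20):
        query = _mutate(query, pos)
    assert match_seed_preserving(query, CANDIDATES) == []


def test_seed_preserving_matches_oracle_on_random_queries():
    rng = np.random.default_rng(5)
    bases = np.array(list("ACGU"))
    for _ in range(200):
        name = rng.choice(sorted(CANDIDATES.matures))
        seq = CANDIDATES.matures[name].sequence
        n_mut = int(rng.integers(0, 4))
        query = list(seq)
        for pos in rng.choice(len(seq), size=n_mut, replace=False):
            query[pos] = str(rng.choice(bases[bases != query[pos]]))
        query = "".join(query)
        assert match_seed_preserving(query, CANDIDATES) == \
            oracle_seed_preserving(query, CANDIDATES)


# ---------------------------------------------------------------------------
# map_genome
# ---------------------------------------------------------------------------

def test_map_genome_plus_strand_plant():
    rng = np.random.default_rng(0)
    contig = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 1000)])
    insert = "ACGTACGTACGTACGTACGTAC"
    genome = {"c": contig[:100] + insert + contig[100:]}
    hits = [h for h in map_genome(insert, genome) if h.strand == "+"]
    assert any(h.start == 100 and h.end == 100 + len(insert) for h in hits)


def test_map_genome_minus_strand_plant():
    rng = np.random.default_rng(1)
    contig = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 500)])
    insert = "AACCGGTTAACCGGTTAACC"
    genome = {"c": contig[:50] + revcomp_dna(insert) + contig[50:]}
    hits = map_genome(insert, genome)
    assert [(h.start, h.end, h.strand) for h in hits] == [(50, 50 + len(insert), "-")]


def test_map_genome_absent():
    assert map_genome("A" * 25, {"c": "CGT" * 100}) == []


# ---------------------------------------------------------------------------
# classify_contaminant
# ---------------------------------------------------------------------------

def test_contaminant_rrna_substring(small_sim):
    _, rs, _, _ = small_sim
    ref = sorted(rs.contaminants["rrna"].values())[0]
    assert classify_contaminant(ref[10:40], rs.contaminants) == "trna_rrna_snrna"


def test_contaminant_precedence_repeat_over_mrna():
    shared = "ACGTTGCAACGTTGCAACGTTGCA"
    contaminants = {
        "repeat": {"r1": "TTTT" + shared + "GGGG"},
        "mrna": {"m1": "CCCC" + shared + "AAAA"},
    }
    assert classify_contaminant(shared, contaminants) == "repeat"


def test_contaminant_no_match():
    assert classify_contaminant("A" * 30, {"repeat": {"r": "CGCG" * 30}}) is None


# ---------------------------------------------------------------------------
# annotate_library and the cascade
# ---------------------------------------------------------------------------

def test_cascade_prefers_chicken_over_human(small_sim):
    _, rs, _, _ = small_sim
    # craft a reference set where the same sequence sits in both tiers
    seq = "CAUCCCCAUUCCACUCCUAGCA"
    human = rs.tiers["human"]
    hsa_name = sorted(human.matures)[0]
    rec = annotate_read(human.matures[hsa_name].sequence, rs)
    assert rec.category == "ortholog_exact"
    rec = annotate_read(seq, rs)  # sequence present in the chicken tier
    assert rec.category == "known_mirna"


def test_empty_library_is_an_error(small_sim):
    _, rs, _, _ = small_sim
    lib = Library(id="empty", species="gga", stage="HH20", reads=[])
    with pytest.raises(ValueError, match="no reads"):
        annotate_library(lib, rs)


def test_partition_and_fraction_sum(small_annotated):
    for records, summary in small_annotated:
        assert all(r.category in CATEGORIES for r in records)
        assert abs(sum(summary.fractions.values()) - 1.0) < 1e-9
        assert all(f >= 0 for f in summary.fractions.values())


def test_summary_fractions_match_planted_truth(small_sim, small_annotated):
    _, _, truth, _ = small_sim
    for records, summary in small_annotated:
        realized = truth.category_counts[summary.library_id]
        total = sum(realized.values())
        for cat in CATEGORIES:
            assert summary.fractions[cat] == pytest.approx(
                realized.get(cat, 0) / total, abs=1e-12
            )


def test_cascade_idempotent(small_sim, small_libraries):
    _, rs, _, _ = small_sim
    lib = small_libraries[0]
    first, _ = annotate_library(lib, rs)
    second, _ = annotate_library(lib, rs)
    assert first == second


def test_category_invariants_on_records(small_annotated):
    for records, _ in small_annotated:
        for r in records:
            if r.category in ("known_mirna", "star_mirna", "ortholog_exact"):
                assert r.assigned_name is not None
                assert r.mismatch_positions == ()
            elif r.category == "ortholog_mismatch":
                assert 1 <= len(r.mismatch_positions) <= 2
                assert not any(2 <= p <= 8 for p in r.mismatch_positions)
            else:
                assert r.assigned_name is None


def test_mismatch_never_fires_with_an_exact_hit(small_sim, small_annotated):
    _, rs, _, _ = small_sim
    for records, _ in small_annotated:
        for r in records:
            if r.category != "ortholog_mismatch":
                continue
            for tier in rs.tiers.values():
                assert match_exact(r.insert, tier) == []


# --- brute-force all-pairs comparator oracle -------------------------------

def oracle_cascade(insert, rs):
    """Enumerate all (read, reference) comparisons with the cascade precedence."""
    q = to_rna(insert)
    chicken = rs.tiers["chicken"]
    names = sorted(n for n, m in chicken.matures.items() if m.sequence == q)
    if names:
        return "known_mirna", names[0]
    annotated = set(chicken.matures)
    for hid in sorted(chicken.hairpins):
        hp = chicken.hairpins[hid]
        for a in sorted(hp.arm_intervals):
            if a not in annotated:
                continue
            for b in sorted(hp.arm_intervals):
                if b == a or b in annotated:
                    continue
                s, e = hp.arm_intervals[b]
                if q in hp.sequence[s:e]:
                    return "star_mirna", a + "-ukstar"
    for tier in ("human", "zebrafinch"):
        cat = rs.tiers[tier]
        names = sorted(n for n, m in cat.matures.items() if m.sequence == q)
        if names:
            return "ortholog_exact", names[0]
    for tier in ("human", "zebrafinch"):
        hits = oracle_seed_preserving(q, rs.tiers[tier])
        if hits:
            hits.sort(key=lambda h: (len(h[1]), h[0]))
            return "ortholog_mismatch", hits[0][0]
    dna = to_dna(q)
    for contig in rs.genome_panel.get("gga", {}).values():
        if dna in contig or revcomp_dna(dna) in contig:
            return "genome_only", None
    for category, classes in (
        ("trna_rrna_snrna", ("trna", "rrna", "snrna")),
        ("repeat", ("repeat",)),
        ("degraded_mrna", ("mrna",)),
    ):
        for cls in classes:
            for seq in rs.contaminants.get(cls, {}).values():
                if dna in seq:
                    return category, None
    return "unannotated", None


def test_cascade_equals_bruteforce_oracle(small_sim, small_libraries):
    _, rs, _, _ = small_sim
    assert sum(len(t.matures) for t in rs.tiers.values()) <= 50
    inserts = {cr.insert for lib in small_libraries for cr in lib.reads}
    assert len(inserts) <= 500
    for insert in sorted(inserts):
        rec = annotate_read(insert, rs)
        cat, name = oracle_cascade(insert, rs)
        assert (rec.category, rec.assigned_name) == (cat, name), insert
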