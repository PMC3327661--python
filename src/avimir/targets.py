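"""Seed-based target prediction (mature positions 2-8) and term enrichment."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Set, Tuple

from scipy.stats import hypergeom

from .refdata import MatureMiRNA, ReferenceSet, UTR
from .seq import revcomp_dna, to_dna

SEED_START, SEED_END = 2, 8  # 1-based inclusive


@dataclass(frozen=True)
class SeedMatchSite:
    mirna: str
    transcript: str
    start: int  # 0-based offset of the 7-nt match in the UTR
    site_type: str  # sevenmer_m8 | eightmer


@dataclass
class TargetPrediction:
    mirna: str
    sites: Dict[str, List[SeedMatchSite]] = field(default_factory=dict)
    n_target_transcripts: int = 0
    target_genes: frozenset = frozenset()


@dataclass
class EnrichmentResult:
    term: str
    k: int
    K: int
    n: int
    N: int
    p_raw: float
    p_adj: float
    significant: bool


def seed_of(m: MatureMiRNA) -> str:
    """Positions 2-8 (1-based, inclusive) of the mature sequence."""
    if len(m.sequence) < SEED_END:
        raise ValueError(f"mature {m.name!r} shorter than {SEED_END} nt has no seed")
    return m.sequence[SEED_START - 1:SEED_END]


def find_sites(seed: str, utr: str, mirna: str = "", transcript: str = "") -> List[SeedMatchSite]:
    """All seed-complement matches in a UTR, overlapping sites included.

    The UTR must contain the reverse complement (DNA space) of the 7-nt seed;
    a site followed by 'A' is an eightmer, otherwise a sevenmer_m8.
    """
    if len(seed) != SEED_END - SEED_START + 1:
        raise ValueError("seed must be exactly 7 nt")
    match = revcomp_dna(to_dna(seed))
    utr = to_dna(utr)
    sites = []
    start = utr.find(match)
    while start != -1:
        nxt = utr[start + 7:start + 8]
        site_type = "eightmer" if nxt == "A" else "sevenmer_m8"
        sites.append(SeedMatchSite(
            mirna=mirna, transcript=transcript, start=start, site_type=site_type,
        ))
        start = utr.find(match, start + 1)
    return sites


def predict_targets(m: MatureMiRNA, utrs: Dict[str, UTR]) -> TargetPrediction:
    """Transcripts carrying at least one seed site, aggregated to genes."""
    if not utrs:
        raise ValueError("UTR set is empty")
    seed = seed_of(m)
    sites: Dict[str, List[SeedMatchSite]] = {}
    genes = set()
    for tx in sorted(utrs):
        utr = utrs[tx]
        hits = find_sites(seed, utr.sequence, mirna=m.name, transcript=tx)
        if hits:
            sites[tx] = hits
            genes.add(utr.gene_id)
    return TargetPrediction(
        mirna=m.name,
        sites=sites,
        n_target_transcripts=len(sites),
        target_genes=frozenset(genes),
    )


def enrich_terms(
    target_genes: Set[str],
    rs: ReferenceSet,
    alpha: float = 0.05,
) -> Tuple[List[EnrichmentResult], int]:
    """Hypergeometric upper-tail enrichment of each term among target genes.

    Universe = every gene with at least one term annotation; target genes
    outside the universe are dropped (their number is returned). p_adj is a
    Bonferroni correction over all terms tested.
    """
    universe = set()
    for genes in rs.terms.values():
        universe |= genes
    if not universe:
        raise ValueError("term-annotation universe is empty")
    in_universe = set(target_genes) & universe
    n_dropped = len(set(target_genes)) - len(in_universe)
    N = len(universe)
    n = len(in_universe)
    m_tests = len(rs.terms)
    results = []
    for term in sorted(rs.terms):
        term_genes = rs.terms[term]
        K = len(term_genes)
        k = len(term_genes & in_universe)
        p_raw = float(hypergeom.sf(k - 1, N, K, n))
        p_raw = min(p_raw, 1.0)
        p_adj = min(1.0, p_raw * m_tests)
        results.append(EnrichmentResult(
            term=term, k=k, K=K, n=n, N=N,
            p_raw=p_raw, p_adj=p_adj, significant=p_adj < alpha,
        ))
    return results, n_dropped


def write_sites(predictions: Iterable[TargetPrediction], path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna\ttranscript\tstart\tsite_type\n")
        for pred in predictions:
            for tx in sorted(pred.sites):
                for s in pred.sites[tx]:
                    fh.write(f"{s.mirna}\t{s.transcript}\t{s.start}\t{s.site_type}\n")


def write_enrichment(results: Iterable[EnrichmentResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("term\tk\tK\tn\tN\tp_raw\tp_adj\tsignificant\n")
        for r in results:
            fh.write(
                f"{r.term}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t{r.p_raw:.6g}\t"
                f"{r.p_adj:.6g}\t{str(r.significant).lower()}\n"
            )
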