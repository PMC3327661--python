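# avimir

Cross-species small-RNA analysis toolkit for avian neural-crest libraries:
from raw small-RNA FASTQ reads to an annotated miRNA catalog (including
inferred star strands and cross-species ortholog rescue), per-million-mapped-
reads quantification, pairwise differential expression across species and
developmental stages, an avian-lineage-specificity screen, and seed-based
target prediction with term enrichment. A first-class synthetic-data module
generates complete experiments (3 species x 2 stages) with planted ground
truth for every pipeline stage.

## Modules

| module | role |
| --- | --- |
| `avimir.refdata` | tiered mature/hairpin catalogs, contaminant sets, genome panel, UTRs, term annotations; FASTA/TSV I/O and validation |
| `avimir.preprocess` | adapter trimming, 20–40 nt size selection, read collapsing |
| `avimir.annotate` | the annotation cascade: known miRNA → star strand → exact ortholog → seed-preserving mismatch ortholog → genome → contaminants → unannotated |
| `avimir.quantify` | miRNA × library count matrix, PMMR normalization, >15 PMMR detection |
| `avimir.diffexpr` | log2 fold change, two-sided Fisher exact test on raw counts, Bonferroni correction, trend classes |
| `avimir.lineage` | avian-only candidate compilation and cross-genome presence/absence screening |
| `avimir.targets` | 7mer-m8/8mer seed-site prediction over 3'UTRs, hypergeometric term enrichment |
| `avimir.simdata` | seeded synthetic reference sets, FASTQ libraries and truth tables |

## CLI

```bash
# generate a synthetic experiment (reference set + FASTQs + truth table)
avimir simulate --seed 1 --out sim --depth 100000

# preprocess -> annotate -> quantify -> differential expression -> trends
avimir run --sim-dir sim --out results

# lineage-specificity screen of the candidate hairpins
avimir lineage --sim-dir sim --out lineage

# seed-based target prediction and term enrichment
avimir targets --sim-dir sim --out targets
```

All outputs are plain TSV/JSON/FASTA; genome coordinates are 0-based
half-open internally.

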