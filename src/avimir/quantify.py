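"""miRNA x library count matrix, PMMR normalization and detection threshold."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Set, Tuple

import pandas as pd

from .annotate import AnnotationRecord, AnnotationSummary, MIRNA_CATEGORIES

PMMR_SCALE = 1_000_000
DEFAULT_DETECTION_PMMR = 15.0


@dataclass
class CountTable:
    """Raw counts (rows: mature names, cols: library ids) plus per-library
    mapped-read denominators."""

    counts: pd.DataFrame
    denominators: Dict[str, int] = field(default_factory=dict)
    ref_fingerprint: str = ""


@dataclass
class PMMRTable:
    values: pd.DataFrame
    denominators: Dict[str, int] = field(default_factory=dict)


def build_count_table(
    annotated: Iterable[Tuple[List[AnnotationRecord], AnnotationSummary]],
) -> CountTable:
    """Aggregate assigned-name counts over the miRNA categories per library.

    All libraries must have been annotated against the same reference set
    (checked via the summary fingerprint); star strands are separate rows.
    """
    per_lib: Dict[str, Dict[str, int]] = {}
    denominators: Dict[str, int] = {}
    fingerprint = None
    for records, summary in annotated:
        if fingerprint is None:
            fingerprint = summary.ref_fingerprint
        elif summary.ref_fingerprint != fingerprint:
            raise ValueError(
                f"library {summary.library_id!r} annotated against a different "
                "reference set"
            )
        col = per_lib.setdefault(summary.library_id, {})
        for rec in records:
            if rec.category in MIRNA_CATEGORIES:
                col[rec.assigned_name] = col.get(rec.assigned_name, 0) + rec.count
        denominators[summary.library_id] = summary.mapped_reads
    names = sorted({n for col in per_lib.values() for n in col})
    libs = list(per_lib)
    df = pd.DataFrame(
        [[per_lib[lib].get(n, 0) for lib in libs] for n in names],
        index=names,
        columns=libs,
        dtype=int,
    )
    return CountTable(counts=df, denominators=denominators, ref_fingerprint=fingerprint or "")


def normalize_pmmr(ct: CountTable) -> PMMRTable:
    """count * 1e6 / mapped-read denominator, per library column."""
    for lib in ct.counts.columns:
        if ct.denominators.get(lib, 0) <= 0:
            raise ValueError(f"library {lib!r} has non-positive mapped-read denominator")
    values = ct.counts.astype(float).copy()
    for lib in values.columns:
        values[lib] = values[lib] * PMMR_SCALE / ct.denominators[lib]
    return PMMRTable(values=values, denominators=dict(ct.denominators))


def detect(pt: PMMRTable, threshold: float = DEFAULT_DETECTION_PMMR) -> Set[str]:
    """Names strictly above ``threshold`` PMMR in at least one library."""
    if threshold < 0:
        raise ValueError("detection threshold must be >= 0")
    if pt.values.empty:
        return set()
    mask = (pt.values > threshold).any(axis=1)
    return set(pt.values.index[mask])


def write_count_table(ct: CountTable, tsv_path, sidecar_json) -> None:
    ct.counts.to_csv(tsv_path, sep="\t", index_label="mirna")
    with open(sidecar_json, "w") as fh:
        json.dump(
            {"denominators": ct.denominators, "ref_fingerprint": ct.ref_fingerprint},
            fh,
            indent=2,
        )


def load_count_table(tsv_path, sidecar_json) -> CountTable:
    df = pd.read_csv(tsv_path, sep="\t", index_col="mirna")
    with open(sidecar_json) as fh:
        meta = json.load(fh)
    return CountTable(
        counts=df.astype(int),
        denominators={k: int(v) for k, v in meta["denominators"].items()},
        ref_fingerprint=meta.get("ref_fingerprint", ""),
    )
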