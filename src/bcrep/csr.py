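"""Class-switch and repertoire composition statistics.

Subclass distributions (percent within the IGG and IGA families),
cross-subclass sequence overlap (transcripts with the exact same CDR1-CDR3
nucleotide sequence observed under two constant genes), and CDR3/gene-usage
summaries for comparing the antigen-experienced repertoire against a naive
one.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .germline import IGA_SUBCLASSES, IGG_SUBCLASSES
from .types import Rearrangement

_FAMILIES = {"IGG": IGG_SUBCLASSES, "IGA": IGA_SUBCLASSES}


def subclass_distribution(
    transcripts: Sequence[Rearrangement],
    strata: Optional[dict[str, str]] = None,
) -> pd.DataFrame:
    """Percent subclass usage within each family, per stratum.

    ``strata`` maps donor_id to a stratum label (e.g. an age group); by
    default each donor is its own stratum.  Strata with no transcripts of a
    family are reported as NaN for that family's subclasses.
    """
    rows: dict[str, dict[str, int]] = {}
    for r in transcripts:
        if r.isotype_class is None:
            continue
        stratum = (strata or {}).get(r.donor_id, r.donor_id)
        rows.setdefault(stratum, {}).setdefault(r.subclass, 0)
        rows[stratum][r.subclass] += 1
    out = []
    for stratum in sorted(rows):
        counts = rows[stratum]
        record: dict[str, object] = {"stratum": stratum}
        for family, subclasses in _FAMILIES.items():
            total = sum(counts.get(sc, 0) for sc in subclasses)
            for sc in subclasses:
                record[sc] = 100.0 * counts.get(sc, 0) / total if total else np.nan
        out.append(record)
    return pd.DataFrame(out)


@dataclass
class OverlapResult:
    stratum: str
    pair: tuple[str, str]
    n_shared: int
    n_family: int

    @property
    def pct_overlap(self) -> float:
        return 100.0 * self.n_shared / self.n_family if self.n_family else 0.0


def cross_subclass_overlap(
    transcripts: Sequence[Rearrangement],
    family: str,
    stratum: str = "",
) -> list[OverlapResult]:
    """Per subclass pair, the percentage of unique CDR1-CDR3 keys of the
    family observed under both subclasses (denominator: all unique family
    keys)."""
    subclasses = _FAMILIES[family]
    keys: dict[str, set[str]] = {sc: set() for sc in subclasses}
    for r in transcripts:
        if r.subclass in keys and r.sequence_key:
            keys[r.subclass].add(r.sequence_key)
    family_keys = set().union(*keys.values())
    results = []
    for a, b in combinations(subclasses, 2):
        results.append(
            OverlapResult(
                stratum=stratum,
                pair=(a, b),
                n_shared=len(keys[a] & keys[b]),
                n_family=len(family_keys),
            )
        )
    return results


def cross_class_overlap(
    transcripts: Sequence[Rearrangement], stratum: str = ""
) -> OverlapResult:
    """IGA x IGG overlap of exact CDR1-CDR3 keys (cross-family table)."""
    keys = {"IGG": set(), "IGA": set()}
    for r in transcripts:
        if r.isotype_class in keys and r.sequence_key:
            keys[r.isotype_class].add(r.sequence_key)
    return OverlapResult(
        stratum=stratum,
        pair=("IGA", "IGG"),
        n_shared=len(keys["IGA"] & keys["IGG"]),
        n_family=len(keys["IGA"] | keys["IGG"]),
    )


def overlap_frame(results: Iterable[OverlapResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "stratum": r.stratum,
                "subclass_a": r.pair[0],
                "subclass_b": r.pair[1],
                "n_shared": r.n_shared,
                "n_family": r.n_family,
                "pct_overlap": r.pct_overlap,
            }
            for r in results
        ]
    )


@dataclass
class RepertoireSummary:
    stratum: str
    n_transcripts: int
    median_cdr3_length_aa: float
    median_junction_deletions: float
    median_n_nucleotides: float
    v_gene_usage: pd.Series  # percent per IGHV gene
    j_gene_usage: pd.Series
    cdr3_aa_composition: pd.Series  # percent per amino acid


def repertoire_summary(
    transcripts: Sequence[Rearrangement], stratum: str = ""
) -> RepertoireSummary:
    """CDR3, junction and gene-usage composition of a transcript set."""
    if not transcripts:
        raise ValueError("no transcripts")
    cdr3_lengths = [len(r.cdr3_aa) for r in transcripts if r.cdr3_aa]
    v_genes = pd.Series([r.v_gene for r in transcripts if r.v_gene])
    j_genes = pd.Series([r.j_gene for r in transcripts if r.j_gene])
    aa_counts: dict[str, int] = {}
    for r in transcripts:
        for aa in r.cdr3_aa:
            aa_counts[aa] = aa_counts.get(aa, 0) + 1
    aa_total = sum(aa_counts.values())
    return RepertoireSummary(
        stratum=stratum,
        n_transcripts=len(transcripts),
        median_cdr3_length_aa=float(np.median(cdr3_lengths)) if cdr3_lengths else np.nan,
        median_junction_deletions=float(
            np.median([r.junction_deletions for r in transcripts])
        ),
        median_n_nucleotides=float(np.median([r.n_nucleotides for r in transcripts])),
        v_gene_usage=(100 * v_genes.value_counts(normalize=True)).sort_index(),
        j_gene_usage=(100 * j_genes.value_counts(normalize=True)).sort_index(),
        cdr3_aa_composition=pd.Series(
            {aa: 100.0 * c / aa_total for aa, c in sorted(aa_counts.items())}
        )
        if aa_total
        else pd.Series(dtype=float),
    )


def compare_summaries(
    naive: RepertoireSummary, experienced: RepertoireSummary
) -> pd.DataFrame:
    """Signed per-metric differences (experienced - naive).

    Gene-usage and amino-acid rows appear as ``v:GENE`` / ``aa:X`` entries;
    a negative sign means the metric is lower in the antigen-experienced
    set.
    """
    rows = [
        ("median_cdr3_length_aa", naive.median_cdr3_length_aa, experienced.median_cdr3_length_aa),
        ("median_junction_deletions", naive.median_junction_deletions, experienced.median_junction_deletions),
        ("median_n_nucleotides", naive.median_n_nucleotides, experienced.median_n_nucleotides),
    ]
    for prefix, a, b in (
        ("v", naive.v_gene_usage, experienced.v_gene_usage),
        ("j", naive.j_gene_usage, experienced.j_gene_usage),
        ("aa", naive.cdr3_aa_composition, experienced.cdr3_aa_composition),
    ):
        for key in sorted(set(a.index) | set(b.index)):
            rows.append((f"{prefix}:{key}", a.get(key, 0.0), b.get(key, 0.0)))
    df = pd.DataFrame(rows, columns=["metric", "naive", "experienced"])
    df["difference"] = df["experienced"] - df["naive"]
    return df


def enforce_naive_uniqueness(transcripts: Sequence[Rearrangement]) -> list[Rearrangement]:
    """Helper constructing the naive-set uniqueness rule: one transcript per
    unique (V gene, J gene, CDR3 amino-acid sequence) combination."""
    seen: set[tuple[str, str, str]] = set()
    out = []
    for r in sorted(transcripts, key=lambda t: t.read_id):
        key = (r.v_gene, r.j_gene, r.cdr3_aa)
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out
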