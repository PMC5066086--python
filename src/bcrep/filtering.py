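"""Read-inclusion rules and the duplicate-collapse sequencing-error filter.

A read survives iff it is productive, complete (CDR1/FR2/CDR2/FR3 all
present), free of ambiguous bases over CDR1..CDR3, and carries a defined
constant-gene subclass; surviving reads are then collapsed on the exact
CDR1..CDR3 nucleotide string plus subclass, and only keys observed two or
more times are retained as unique transcripts.  Donor strata (donor x IGG /
IGA class) with fewer than 45 unique transcripts are excluded from
analysis.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .types import Rearrangement

DEFAULT_MIN_DUPLICATE = 2
DEFAULT_MIN_UNIQUE = 45

#: Fixed step order of the quality filter chain.
FILTER_STEPS = (
    "n_input",
    "n_productive",
    "n_complete",
    "n_no_ambiguous",
    "n_subclass_defined",
    "n_unique_ge2",
)


@dataclass
class FilterReport:
    """Per donor x isotype-class counts after each filtering step."""

    donor_id: str
    isotype_class: str  # "IGG" | "IGA" | "NA" (subclass never defined)
    n_input: int = 0
    n_productive: int = 0
    n_complete: int = 0
    n_no_ambiguous: int = 0
    n_subclass_defined: int = 0
    n_unique_ge2: int = 0
    included: bool = False

    def counts(self) -> list[int]:
        return [getattr(self, step) for step in FILTER_STEPS]


def collapse_duplicates(
    rearrangements: Iterable[Rearrangement], min_duplicate: int = DEFAULT_MIN_DUPLICATE
) -> list[Rearrangement]:
    """Collapse reads sharing the exact CDR1..CDR3 sequence and subclass.

    One representative per key (first by read_id sort) carries
    ``duplicate_count``; keys seen fewer than ``min_duplicate`` times are
    discarded as presumptive sequencing errors.
    """
    groups: dict[tuple[str, str], list[Rearrangement]] = {}
    for r in rearrangements:
        groups.setdefault(r.duplicate_key, []).append(r)
    out = []
    for members in groups.values():
        count = sum(m.duplicate_count for m in members)
        if count < min_duplicate:
            continue
        rep = dataclasses.replace(min(members, key=lambda m: m.read_id))
        rep.duplicate_count = count
        out.append(rep)
    out.sort(key=lambda r: r.read_id)
    return out


def apply_quality_filters(
    rearrangements: Iterable[Rearrangement],
    min_duplicate: int = DEFAULT_MIN_DUPLICATE,
) -> tuple[list[Rearrangement], list[FilterReport]]:
    """Apply the inclusion chain and duplicate collapse, per donor x class.

    Step order: productivity -> completeness -> ambiguity -> subclass ->
    duplicate collapse.  Reads whose subclass is never defined form the
    ``NA`` stratum of the report (they cannot be attributed to IGG/IGA).
    """
    strata: dict[tuple[str, str], list[Rearrangement]] = {}
    for r in rearrangements:
        cls = r.isotype_class or "NA"
        strata.setdefault((r.donor_id, cls), []).append(r)

    survivors: list[Rearrangement] = []
    reports: list[FilterReport] = []
    for (donor, cls), records in sorted(strata.items()):
        rep = FilterReport(donor_id=donor, isotype_class=cls, n_input=len(records))
        step1 = [r for r in records if r.productive]
        rep.n_productive = len(step1)
        step2 = [r for r in step1 if r.complete]
        rep.n_complete = len(step2)
        step3 = [r for r in step2 if not r.has_ambiguous_base]
        rep.n_no_ambiguous = len(step3)
        step4 = [r for r in step3 if r.isotype_class is not None]
        rep.n_subclass_defined = len(step4)
        unique = collapse_duplicates(step4, min_duplicate=min_duplicate)
        rep.n_unique_ge2 = len(unique)
        reports.append(rep)
        survivors.extend(unique)
    return survivors, reports


def filter_donors(
    unique_transcripts: Iterable[Rearrangement],
    min_unique: int = DEFAULT_MIN_UNIQUE,
    reports: Optional[list[FilterReport]] = None,
) -> tuple[list[Rearrangement], set[tuple[str, str]]]:
    """Keep only donor x class strata with >= ``min_unique`` unique transcripts.

    Returns the retained transcripts and the included (donor, class) set;
    when ``reports`` is given its ``included`` flags are filled in.
    """
    counts: dict[tuple[str, str], int] = {}
    for r in unique_transcripts:
        key = (r.donor_id, r.isotype_class or "NA")
        counts[key] = counts.get(key, 0) + 1
    included = {k for k, n in counts.items() if n >= min_unique and k[1] != "NA"}
    if reports is not None:
        for rep in reports:
            rep.included = (rep.donor_id, rep.isotype_class) in included
    kept = [
        r
        for r in unique_transcripts
        if (r.donor_id, r.isotype_class or "NA") in included
    ]
    return kept, included


def filter_report_frame(reports: Iterable[FilterReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "donor_id": rep.donor_id,
                "isotype_class": rep.isotype_class,
                **{step: getattr(rep, step) for step in FILTER_STEPS},
                "included": rep.included,
            }
            for rep in reports
        ]
    )
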