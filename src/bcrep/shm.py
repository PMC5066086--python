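"""Somatic-hypermutation profiling.

Substitution mutations are called against the germline V over IMGT codons
27-104 (CDR1 start through FR3 end): FR1 is excluded because the forward
primers sit there, and the CDR3/junction is excluded because N-region bases
have no defined germline.  Each mutation is classified by substitution type
(transition/transversion), strand-agnostic base class (A/T vs G/C),
AID-hotspot context (the targeted G of RGYW / C of WRCY, the A of WA / T of
TW, evaluated on the germline strand), and replacement/silent effect on the
germline codon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .germline import (
    ANALYSIS_NT_SPAN,
    CDR1_SPAN,
    CDR_REGIONS,
    FR3_SPAN,
    FR_REGIONS,
    GermlineDatabase,
    GermlineSegment,
    NUCLEOTIDES,
    PURINES,
    TRANSITION_PARTNER,
    codon_nt_span,
    default_germline_db,
    region_of_nt,
    translate,
)
from .types import Rearrangement


@dataclass(frozen=True)
class Mutation:
    """One substitution versus the germline V."""

    position: int  # 1-based nucleotide position in the germline V
    from_base: str
    to_base: str
    region: str  # CDR1 | FR2 | CDR2 | FR3
    is_transition: bool
    at_gc: bool
    in_rgyw_wrcy: bool
    in_wa_tw: bool
    rs_class: str  # "R" | "S"

    def __post_init__(self) -> None:
        if self.from_base == self.to_base:
            raise ValueError("from_base must differ from to_base")


def classify_substitution(from_base: str, to_base: str) -> tuple[bool, bool]:
    """(is_transition, at_gc) for a substitution; raises when from == to."""
    if from_base == to_base:
        raise ValueError("not a substitution: bases are equal")
    is_transition = (from_base in PURINES) == (to_base in PURINES)
    return is_transition, from_base in "GC"


_W = set("AT")
_R = set("AG")
_Y = set("CT")


def flag_hotspots(germline_seq: str, position: int) -> tuple[bool, bool]:
    """Hotspot context of a 1-based germline position.

    ``in_rgyw_wrcy``: the position is the targeted G of an RGYW 4-mer or
    the targeted C of a WRCY 4-mer.  ``in_wa_tw``: the position is the A of
    a WA 2-mer or the T of a TW 2-mer.  All motifs are evaluated on the
    germline strand as written.
    """
    i = position - 1
    s = germline_seq
    base = s[i]
    rgyw = (
        base == "G"
        and i >= 1
        and i + 2 < len(s)
        and s[i - 1] in _R
        and s[i + 1] in _Y
        and s[i + 2] in _W
    )
    wrcy = (
        base == "C"
        and i >= 2
        and i + 1 < len(s)
        and s[i - 2] in _W
        and s[i - 1] in _R
        and s[i + 1] in _Y
    )
    wa = base == "A" and i >= 1 and s[i - 1] in _W
    tw = base == "T" and i + 1 < len(s) and s[i + 1] in _W
    return (rgyw or wrcy), (wa or tw)


def hotspot_mask(germline_seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized hotspot flags for every position of a germline sequence."""
    n = len(germline_seq)
    rgyw_wrcy = np.zeros(n, dtype=bool)
    wa_tw = np.zeros(n, dtype=bool)
    for i in range(n):
        rgyw_wrcy[i], wa_tw[i] = flag_hotspots(germline_seq, i + 1)
    return rgyw_wrcy, wa_tw


def classify_rs(germline_codon: str, position_in_codon: int, to_base: str) -> str:
    """Replacement/silent class of a single substitution within a codon.

    Only the named position (1-3) is substituted into the germline codon;
    a mutation creating a stop codon counts as replacement.
    """
    aa_before = translate(germline_codon)
    mutated = (
        germline_codon[: position_in_codon - 1]
        + to_base
        + germline_codon[position_in_codon:]
    )
    return "S" if translate(mutated) == aa_before else "R"


def call_mutations(
    rearrangement: Rearrangement, germline_v: GermlineSegment
) -> list[Mutation]:
    """Mutations of a transcript vs its germline V over codons 27-104."""
    muts, _ = mutation_scan(rearrangement, germline_v)
    return muts


def mutation_scan(
    rearrangement: Rearrangement, germline_v: GermlineSegment
) -> tuple[list[Mutation], int]:
    """(mutations, n_bases_compared) over the analysis span.

    Reads flagged ``has_indel`` yield no calls (flag propagated upstream);
    positions where either base is ambiguous are skipped and excluded from
    the denominator.
    """
    if rearrangement.has_indel:
        return [], 0
    lo, hi = ANALYSIS_NT_SPAN
    lo = max(lo, rearrangement.v_germ_start)
    hi = min(hi, rearrangement.v_germ_end)
    seq = germline_v.sequence
    mutations: list[Mutation] = []
    n_compared = 0
    for pos in range(lo, hi + 1):
        read_base = rearrangement.read_base_at_v(pos)
        germ_base = seq[pos - 1]
        if read_base is None or read_base not in NUCLEOTIDES or germ_base not in NUCLEOTIDES:
            continue
        n_compared += 1
        if read_base == germ_base:
            continue
        region = region_of_nt(pos)
        if region is None or region == "FR1":
            continue
        is_transition, at_gc = classify_substitution(germ_base, read_base)
        rgyw_wrcy, wa_tw = flag_hotspots(seq, pos)
        codon_idx = (pos - 1) // 3
        codon = seq[codon_idx * 3 : codon_idx * 3 + 3]
        pos_in_codon = (pos - 1) % 3 + 1
        mutations.append(
            Mutation(
                position=pos,
                from_base=germ_base,
                to_base=read_base,
                region=region,
                is_transition=is_transition,
                at_gc=at_gc,
                in_rgyw_wrcy=rgyw_wrcy,
                in_wa_tw=wa_tw,
                rs_class=classify_rs(codon, pos_in_codon, read_base),
            )
        )
    return mutations, n_compared


def build_transition_table(mutations: Iterable[Mutation]) -> pd.DataFrame:
    """4x4 substitution-count matrix (rows germline base, columns observed)."""
    table = pd.DataFrame(
        0, index=list(NUCLEOTIDES), columns=list(NUCLEOTIDES), dtype=int
    )
    for m in mutations:
        table.loc[m.from_base, m.to_base] += 1
    return table


def transition_table_percent(table: pd.DataFrame) -> pd.DataFrame:
    """Normalized (percentage of all mutations) table, sunburst-ready."""
    total = table.values.sum()
    if total == 0:
        return table.astype(float)
    return 100.0 * table / total


def sunburst_export(table: pd.DataFrame) -> dict:
    """Nested-percentage dict for sunburst plots.

    Inner ring: germline base (percent of all mutations); outer ring: the
    newly incorporated base (percent of all mutations, nested under its
    germline base).
    """
    pct = transition_table_percent(table)
    return {
        germ: {
            "pct": float(pct.loc[germ].sum()),
            "observed": {
                obs: float(pct.loc[germ, obs])
                for obs in pct.columns
                if obs != germ
            },
        }
        for germ in pct.index
    }


@dataclass
class RSRatio:
    n_r: int
    n_s: int

    @property
    def ratio(self) -> Optional[float]:
        if self.n_s == 0:
            return None
        return self.n_r / self.n_s


def rs_ratio(mutations: Iterable[Mutation], region_set: frozenset[str]) -> RSRatio:
    """Replacement/silent ratio over mutations in ``region_set``.

    Undefined (None ratio) when no silent mutations; both counts are always
    reported.
    """
    n_r = n_s = 0
    for m in mutations:
        if m.region in region_set:
            if m.rs_class == "R":
                n_r += 1
            else:
                n_s += 1
    return RSRatio(n_r, n_s)


def positional_r_profile(
    per_transcript_mutations: Sequence[Sequence[Mutation]],
) -> pd.Series:
    """Per-IMGT-codon fraction of transcripts carrying >= 1 R mutation there."""
    if not per_transcript_mutations:
        raise ValueError("needs at least one transcript")
    codons = range(CDR1_SPAN[0], FR3_SPAN[1] + 1)
    counts = {c: 0 for c in codons}
    for muts in per_transcript_mutations:
        seen = {(m.position - 1) // 3 + 1 for m in muts if m.rs_class == "R"}
        for c in seen:
            if c in counts:
                counts[c] += 1
    n = len(per_transcript_mutations)
    return pd.Series({c: counts[c] / n for c in codons}, name="r_frequency")


@dataclass
class SHMProfile:
    """Per-donor (x isotype class) aggregate SHM statistics."""

    donor_id: str
    isotype_class: str
    n_transcripts: int
    n_mutations: int
    n_bases_compared: int
    pct_mutation: float
    pct_rgyw_wrcy: float
    pct_wa_tw: float
    pct_at: float
    pct_gc: float
    pct_gc_transitions: float
    pct_transitions: float
    transition_table: pd.DataFrame
    region_rs_counts: dict[str, tuple[int, int]]
    rs_cdr: RSRatio = field(default=None)  # type: ignore[assignment]
    rs_fr: RSRatio = field(default=None)  # type: ignore[assignment]

    @property
    def rs_ratio_cdr(self) -> Optional[float]:
        return self.rs_cdr.ratio

    @property
    def rs_ratio_fr(self) -> Optional[float]:
        return self.rs_fr.ratio


def _pct(num: int, denom: int) -> float:
    return 100.0 * num / denom if denom else 0.0


def shm_profile(
    donor_id: str,
    isotype_class: str,
    transcripts: Sequence[Rearrangement],
    db: Optional[GermlineDatabase] = None,
) -> SHMProfile:
    """Aggregate mutation statistics for one donor x class stratum.

    Indel-flagged transcripts contribute neither mutations nor denominator.
    """
    db = db if db is not None else default_germline_db()
    all_mutations: list[Mutation] = []
    n_bases = 0
    for r in transcripts:
        if not r.v_call or r.v_call[0] not in db:
            continue
        muts, compared = mutation_scan(r, db[r.v_call[0]])
        all_mutations.extend(muts)
        n_bases += compared
    n = len(all_mutations)
    n_gc = sum(m.at_gc for m in all_mutations)
    n_gc_ts = sum(m.at_gc and m.is_transition for m in all_mutations)
    region_rs: dict[str, tuple[int, int]] = {}
    for region in ("CDR1", "FR2", "CDR2", "FR3"):
        rr = rs_ratio(all_mutations, frozenset({region}))
        region_rs[region] = (rr.n_r, rr.n_s)
    return SHMProfile(
        donor_id=donor_id,
        isotype_class=isotype_class,
        n_transcripts=len(transcripts),
        n_mutations=n,
        n_bases_compared=n_bases,
        pct_mutation=_pct(n, n_bases),
        pct_rgyw_wrcy=_pct(sum(m.in_rgyw_wrcy for m in all_mutations), n),
        pct_wa_tw=_pct(sum(m.in_wa_tw for m in all_mutations), n),
        pct_at=_pct(n - n_gc, n),
        pct_gc=_pct(n_gc, n),
        pct_gc_transitions=_pct(n_gc_ts, n_gc),
        pct_transitions=_pct(sum(m.is_transition for m in all_mutations), n),
        transition_table=build_transition_table(all_mutations),
        region_rs_counts=region_rs,
        rs_cdr=rs_ratio(all_mutations, CDR_REGIONS),
        rs_fr=rs_ratio(all_mutations, FR_REGIONS),
    )


def profile_frame(profiles: Sequence[SHMProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        rows.append(
            {
                "donor_id": p.donor_id,
                "isotype_class": p.isotype_class,
                "n_transcripts": p.n_transcripts,
                "n_mutations": p.n_mutations,
                "n_bases_compared": p.n_bases_compared,
                "pct_mutation": p.pct_mutation,
                "pct_rgyw_wrcy": p.pct_rgyw_wrcy,
                "pct_wa_tw": p.pct_wa_tw,
                "pct_at": p.pct_at,
                "pct_gc": p.pct_gc,
                "pct_gc_transitions": p.pct_gc_transitions,
                "pct_transitions": p.pct_transitions,
                "r_cdr": p.rs_cdr.n_r,
                "s_cdr": p.rs_cdr.n_s,
                "r_fr": p.rs_fr.n_r,
                "s_fr": p.rs_fr.n_s,
                "rs_ratio_cdr": p.rs_ratio_cdr,
                "rs_ratio_fr": p.rs_ratio_fr,
            }
        )
    return pd.DataFrame(rows)
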