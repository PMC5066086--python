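"""Antigen-selection statistics.

Per transcript, an IgAT-style one-sided binomial test asks whether the
number of replacement mutations in the CDRs (R_CDR) is larger than expected
given the transcript's total mutation count (M_v) and a null probability p
obtained by exhaustively enumerating every possible substitution of the
germline V over the analysis span.  Per donor, a simplified log-odds
selection strength (a documented substitute for the full Bayesian BASELINe
posterior) contrasts observed versus expected replacement fractions per
region with a 0.5 pseudocount and a nonparametric bootstrap CI.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .germline import (
    ANALYSIS_NT_SPAN,
    CDR_REGIONS,
    FR_REGIONS,
    GermlineDatabase,
    GermlineSegment,
    NUCLEOTIDES,
    default_germline_db,
    region_of_nt,
)
from .shm import Mutation, classify_rs, flag_hotspots, mutation_scan
from .types import Rearrangement

DEFAULT_ALPHA = 0.05


@dataclass
class SelectionResult:
    read_id: str
    r_cdr: int
    m_v: int
    p_expected_r_cdr: float
    p_value: float
    selected: bool


@dataclass
class SelectionStrengthSummary:
    donor_id: str
    region: str  # "CDR" | "FR"
    strength: float
    ci_low: float
    ci_high: float
    n_transcripts: int


def _enumerate_substitutions(
    germline_v: GermlineSegment,
    region_set: Optional[frozenset[str]] = None,
    hotspot_weight: float = 1.0,
):
    """Yield (region, is_replacement, weight) for all 3 substitutions at
    every analyzed germline position (codons 27-104)."""
    seq = germline_v.sequence
    lo, hi = ANALYSIS_NT_SPAN
    for pos in range(lo, hi + 1):
        region = region_of_nt(pos)
        if region is None or region == "FR1":
            continue
        if region_set is not None and region not in region_set:
            continue
        germ_base = seq[pos - 1]
        weight = 1.0
        if hotspot_weight != 1.0:
            rgyw_wrcy, wa_tw = flag_hotspots(seq, pos)
            if rgyw_wrcy or wa_tw:
                weight = hotspot_weight
        codon_idx = (pos - 1) // 3
        codon = seq[codon_idx * 3 : codon_idx * 3 + 3]
        pos_in_codon = (pos - 1) % 3 + 1
        for to_base in NUCLEOTIDES:
            if to_base == germ_base:
                continue
            is_r = classify_rs(codon, pos_in_codon, to_base) == "R"
            yield region, is_r, weight


def expected_r_cdr_probability(
    germline_v: GermlineSegment,
    region_mask: Optional[frozenset[str]] = None,
    hotspot_weight: float = 1.0,
) -> float:
    """Null probability that a random mutation is a CDR replacement.

    All 3 possible substitutions at every analyzed germline position are
    enumerated; p = (replacement substitutions in CDR) / (all
    substitutions), optionally weighting hotspot-flagged positions by
    ``hotspot_weight``.  ``region_mask`` names the regions counted as CDR
    (default CDR1+CDR2); a mask without CDR positions is a degenerate null
    and raises.
    """
    cdr = region_mask if region_mask is not None else CDR_REGIONS
    num = denom = 0.0
    n_cdr_positions = 0
    for region, is_r, weight in _enumerate_substitutions(
        germline_v, None, hotspot_weight
    ):
        denom += weight
        if region in cdr:
            n_cdr_positions += 1
            if is_r:
                num += weight
    if n_cdr_positions == 0:
        raise ValueError("degenerate null: region mask contains no CDR positions")
    return num / denom


def expected_replacement_fraction(
    germline_v: GermlineSegment, region_set: frozenset[str]
) -> float:
    """Fraction of possible substitutions within ``region_set`` that are replacement."""
    n = r = 0
    for _, is_r, _ in _enumerate_substitutions(germline_v, region_set):
        n += 1
        r += is_r
    if n == 0:
        raise ValueError("region set covers no analyzed positions")
    return r / n


def antigen_selection_pvalue(r_cdr: int, m_v: int, p: float) -> float:
    """Upper-tail binomial P(X >= r_cdr | m_v, p); no mutations -> 1."""
    if r_cdr < 0 or r_cdr > m_v:
        raise ValueError("require 0 <= r_cdr <= m_v")
    if m_v == 0 or r_cdr == 0:
        return 1.0
    return float(stats.binom.sf(r_cdr - 1, m_v, p))


def analyze_selection(
    transcripts: Sequence[Rearrangement],
    db: Optional[GermlineDatabase] = None,
    alpha: float = DEFAULT_ALPHA,
) -> list[SelectionResult]:
    """Per-transcript antigen-selection calls (one-sided, no correction)."""
    db = db if db is not None else default_germline_db()
    p_cache: dict[str, float] = {}
    results = []
    for r in transcripts:
        if not r.v_call or r.v_call[0] not in db or r.has_indel:
            continue
        v = db[r.v_call[0]]
        if v.name not in p_cache:
            p_cache[v.name] = expected_r_cdr_probability(v)
        muts, _ = mutation_scan(r, v)
        m_v = len(muts)
        r_cdr = sum(m.rs_class == "R" and m.region in CDR_REGIONS for m in muts)
        p_val = antigen_selection_pvalue(r_cdr, m_v, p_cache[v.name])
        results.append(
            SelectionResult(
                read_id=r.read_id,
                r_cdr=r_cdr,
                m_v=m_v,
                p_expected_r_cdr=p_cache[v.name],
                p_value=p_val,
                selected=p_val < alpha,
            )
        )
    return results


def fraction_selected(
    selection_results: Sequence[SelectionResult], alpha: float = DEFAULT_ALPHA
) -> float:
    """Percentage of transcripts called antigen-selected at ``alpha``."""
    if not selection_results:
        raise ValueError("no selection results")
    n_sel = sum(r.p_value < alpha for r in selection_results)
    return 100.0 * n_sel / len(selection_results)


def _log_odds_strength(r_obs: float, e_r: float, n: float) -> float:
    return log((r_obs + 0.5) / (e_r + 0.5)) - log((n - r_obs + 0.5) / (n - e_r + 0.5))


def selection_strength(
    per_transcript_mutations: Sequence[Sequence[Mutation]],
    region: str,
    p_expected: float,
    donor_id: str = "",
    n_bootstrap: int = 1000,
    rng: Optional[np.random.Generator] = None,
) -> SelectionStrengthSummary:
    """Log-odds selection strength for CDR or FR with bootstrap CI.

    ``p_expected`` is the expected replacement fraction among mutations in
    the region (from :func:`expected_replacement_fraction`); N counts the
    observed mutations attributable to the region.  Strength is 0 when the
    observed replacement count equals expectation, positive under
    replacement enrichment.
    """
    if region == "CDR":
        region_set = CDR_REGIONS
    elif region == "FR":
        region_set = FR_REGIONS
    else:
        raise ValueError("region must be 'CDR' or 'FR'")
    rng = rng if rng is not None else np.random.default_rng(0)

    # per-transcript (replacement, total) mutation counts in the region
    r_i = np.array(
        [
            sum(m.region in region_set and m.rs_class == "R" for m in muts)
            for muts in per_transcript_mutations
        ]
    )
    n_i = np.array(
        [sum(m.region in region_set for m in muts) for muts in per_transcript_mutations]
    )
    r_obs, n = int(r_i.sum()), int(n_i.sum())
    strength = _log_odds_strength(r_obs, n * p_expected, n) if n else 0.0

    k = len(per_transcript_mutations)
    idx = rng.integers(0, k, size=(n_bootstrap, k))
    rb = r_i[idx].sum(axis=1).astype(float)
    nb = n_i[idx].sum(axis=1).astype(float)
    keep = nb > 0
    rb, nb = rb[keep], nb[keep]
    if rb.size:
        eb = nb * p_expected
        boots = np.log((rb + 0.5) / (eb + 0.5)) - np.log((nb - rb + 0.5) / (nb - eb + 0.5))
        ci_low, ci_high = np.percentile(boots, [2.5, 97.5])
    else:
        ci_low = ci_high = strength
    return SelectionStrengthSummary(
        donor_id=donor_id,
        region=region,
        strength=strength,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_transcripts=k,
    )
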