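"""Internal germline annotator.

A deliberately simple scoring annotator over the packaged toy germline set:
candidate V/J genes are ranked by global(gene)-local(read) alignment
distance (edlib), the best candidate is then aligned precisely with
Biopython's PairwiseAligner to obtain per-position germline-read
correspondence, IMGT regions are sliced from that mapping, and the junction
is delimited by the conserved Cys codon (V codon 104) and the J-frame Trp.
Users with real data are expected to supply AIRR TSV from a full external
annotator; this one exists so the pipeline is testable end to end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import edlib
from Bio import Align

from .germline import (
    ANALYSIS_REGIONS,
    GermlineDatabase,
    GermlineSegment,
    REGION_CODON_SPANS,
    V_CORE_NT,
    codon_nt_span,
    default_germline_db,
    translate,
)
from .io import RawRead
from .types import Rearrangement, UNDEFINED, scan_ambiguous

DEFAULT_TRIM = 40
#: Maximal edit distance (fraction of gene length) for a V assignment.
MAX_V_EDIT_FRACTION = 0.35
MAX_J_EDIT_FRACTION = 0.40
#: Minimal exact-substring length to attribute junction bases to a D gene.
MIN_D_MATCH = 6


def trim_flanks(
    sequence: str, n_left: int = DEFAULT_TRIM, n_right: int = DEFAULT_TRIM
) -> Optional[str]:
    """Remove primer flanks; returns None (read dropped) when too short."""
    if len(sequence) <= n_left + n_right:
        return None
    return sequence[n_left : len(sequence) - n_right]


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -6
    aligner.extend_gap_score = -1
    return aligner


@dataclass
class VAlignment:
    """Gap-aware mapping of a read onto a germline V."""

    v_name: str
    score: float
    has_indel: bool
    # parallel aligned blocks: (read_start, read_end) / (germ_start, germ_end), 0-based half-open
    read_blocks: list[tuple[int, int]]
    germ_blocks: list[tuple[int, int]]

    def read_index_of(self, germ_pos: int) -> Optional[int]:
        """0-based read index aligned to 1-based germline position."""
        g = germ_pos - 1
        for (rs, _), (gs, ge) in zip(self.read_blocks, self.germ_blocks):
            if gs <= g < ge:
                return rs + (g - gs)
        return None

    @property
    def germ_start(self) -> int:  # 1-based
        return self.germ_blocks[0][0] + 1

    @property
    def germ_end(self) -> int:  # 1-based inclusive
        return self.germ_blocks[-1][1]

    @property
    def read_start(self) -> int:
        return self.read_blocks[0][0]

    @property
    def read_end(self) -> int:  # 0-based exclusive
        return self.read_blocks[-1][1]


def _edit_distance(query: str, target: str) -> int:
    return edlib.align(query, target, mode="HW", task="distance")["editDistance"]


def rank_segments(
    read: str, segments: Sequence[GermlineSegment], max_fraction: float
) -> list[tuple[str, int]]:
    """Rank germline segments by infix edit distance; ties keep database order."""
    scored = []
    for idx, seg in enumerate(segments):
        dist = _edit_distance(seg.sequence, read)
        if dist <= max_fraction * len(seg.sequence):
            scored.append((dist, idx, seg.name))
    scored.sort(key=lambda t: (t[0], t[1]))
    return [(name, dist) for dist, _, name in scored]


class Annotator:
    """Assign germline genes, regions, junction, productivity and subclass."""

    def __init__(self, db: Optional[GermlineDatabase] = None):
        self.db = db if db is not None else default_germline_db()
        self._aligner = _make_aligner()

    # -- V / J assignment ---------------------------------------------------

    def assign_v(self, read: str) -> tuple[list[str], Optional[VAlignment]]:
        """Ordered V candidate list (best first) and the top alignment."""
        ranked = rank_segments(read, self.db.v_segments, MAX_V_EDIT_FRACTION)
        if not ranked:
            return [], None
        v_call = [name for name, _ in ranked]
        top = self.db[v_call[0]]
        aln = self._aligner.align(read, top.sequence)[0]
        read_blocks, germ_blocks = aln.aligned
        read_blocks = [(int(b[0]), int(b[1])) for b in read_blocks]
        germ_blocks = [(int(b[0]), int(b[1])) for b in germ_blocks]
        # Gaps strictly past the V core (nt > 312) are junction-attribution
        # artifacts (a trimmed 3' tail chance-matching N bases), not real
        # indels: truncate the alignment at the end of the core-covering block.
        if len(germ_blocks) > 1 and germ_blocks[0][1] >= V_CORE_NT:
            read_blocks, germ_blocks = read_blocks[:1], germ_blocks[:1]
        return v_call, VAlignment(
            v_name=top.name,
            score=aln.score,
            has_indel=len(read_blocks) > 1,
            read_blocks=read_blocks,
            germ_blocks=germ_blocks,
        )

    def assign_j(self, read_tail: str) -> tuple[list[str], Optional[VAlignment]]:
        ranked = rank_segments(read_tail, self.db.j_segments, MAX_J_EDIT_FRACTION)
        if not ranked:
            return [], None
        j_call = [name for name, _ in ranked]
        top = self.db[j_call[0]]
        aln = self._aligner.align(read_tail, top.sequence)[0]
        read_blocks, germ_blocks = aln.aligned
        return j_call, VAlignment(
            v_name=top.name,
            score=aln.score,
            has_indel=len(read_blocks) > 1,
            read_blocks=[(int(b[0]), int(b[1])) for b in read_blocks],
            germ_blocks=[(int(b[0]), int(b[1])) for b in germ_blocks],
        )

    # -- regions ------------------------------------------------------------

    def locate_regions(self, read: str, v_aln: VAlignment) -> dict[str, str]:
        """Read substrings for CDR1/FR2/CDR2/FR3 (IMGT codons); missing regions omitted.

        FR1 content is recorded as well but is excluded from all downstream
        mutation analysis.
        """
        regions: dict[str, str] = {}
        for region in ("FR1",) + ANALYSIS_REGIONS:
            lo_codon, hi_codon = REGION_CODON_SPANS[region]
            lo_nt = codon_nt_span(lo_codon)[0]
            hi_nt = codon_nt_span(hi_codon)[1]
            start = v_aln.read_index_of(lo_nt)
            end = v_aln.read_index_of(hi_nt)
            if region == "FR1":
                # partial FR1 is expected after primer trimming
                if end is not None:
                    first = v_aln.read_index_of(max(lo_nt, v_aln.germ_start))
                    if first is not None:
                        regions["FR1"] = read[first : end + 1]
                continue
            if start is None or end is None:
                continue
            regions[region] = read[start : end + 1]
        return regions

    # -- junction -----------------------------------------------------------

    def locate_junction(
        self, read: str, v_aln: VAlignment
    ) -> Optional[dict]:
        """Delimit the junction (Cys-104 .. J-Trp-118) and decompose it.

        Returns None when either conserved anchor cannot be located, in
        which case the read is marked incomplete downstream.
        """
        v_seg = self.db[v_aln.v_name]
        cys_start_nt = codon_nt_span(104)[0]  # germline nt 310
        cys_idx = v_aln.read_index_of(cys_start_nt)
        if cys_idx is None or v_aln.germ_end < V_CORE_NT:
            return None
        cys_codon = read[cys_idx : cys_idx + 3]
        if len(cys_codon) < 3 or translate(cys_codon) != "C":
            return None

        tail_start = v_aln.read_end
        j_call, j_aln = self.assign_j(read[tail_start:])
        if j_aln is None:
            return None
        j_seg = self.db[j_call[0]]
        anchor_off = j_seg.anchor_offset  # 0-based within J
        # read index of the J anchor codon
        rel = j_aln.read_index_of(anchor_off + 1)
        if rel is None:
            return None
        anchor_idx = tail_start + rel
        if read[anchor_idx : anchor_idx + 3] != "TGG":
            return None
        junction_end = anchor_idx + 3  # exclusive
        junction_nt = read[cys_idx:junction_end]

        v_del = len(v_seg.sequence) - v_aln.germ_end
        j_del = j_aln.germ_start - 1
        interior = read[v_aln.read_end : tail_start + j_aln.read_start]

        d_call, d5, d3, matched = self._match_d(interior)
        n_nucleotides = len(interior) - matched
        junction_deletions = v_del + j_del + (d5 + d3 if d_call else 0)

        cdr3_nt = junction_nt[3:-3]
        cdr3_aa = ""
        if len(cdr3_nt) % 3 == 0 and cdr3_nt and not scan_ambiguous(cdr3_nt):
            cdr3_aa = translate(cdr3_nt)
        return {
            "junction_nt": junction_nt,
            "junction_start": cys_idx,
            "junction_end": junction_end,
            "cdr3_nt": cdr3_nt,
            "cdr3_aa": cdr3_aa,
            "j_call": j_call,
            "d_call": d_call,
            "n_nucleotides": n_nucleotides,
            "junction_deletions": junction_deletions,
        }

    def _match_d(self, interior: str) -> tuple[list[str], int, int, int]:
        """Attribute junction-interior bases to a D gene by longest exact substring."""
        best = ("", 0, 0, 0)  # name, d5, d3, match_len
        for seg in self.db.d_segments:
            d = seg.sequence
            for length in range(min(len(d), len(interior)), MIN_D_MATCH - 1, -1):
                found = False
                for off in range(len(d) - length + 1):
                    sub = d[off : off + length]
                    if sub in interior:
                        if length > best[3]:
                            best = (seg.name, off, len(d) - off - length, length)
                        found = True
                        break
                if found:
                    break
        name, d5, d3, matched = best
        return ([name] if name else []), d5, d3, matched

    # -- productivity and subclass -------------------------------------------

    @staticmethod
    def is_productive(read: str, cdr1_start: int, junction: dict) -> bool:
        """In-frame junction and no stop codon over codons 27..118 of the read."""
        if len(junction["junction_nt"]) % 3 != 0:
            return False
        span = read[cdr1_start : junction["junction_end"]]
        if len(span) % 3 != 0 or scan_ambiguous(span):
            return False
        return "*" not in translate(span)

    def assign_subclass(self, read_tail: str) -> str:
        """Exact constant-region motif match; zero or multiple hits -> UNDEFINED."""
        if len(read_tail) < 15:
            return UNDEFINED
        hits = [sc for sc, motif in self.db.subclass_motifs.items() if motif in read_tail]
        return hits[0] if len(hits) == 1 else UNDEFINED

    # -- full annotation ----------------------------------------------------

    def annotate_read(self, read_id: str, donor_id: str, sequence: str) -> Optional[Rearrangement]:
        """Annotate one (already primer-trimmed) read; None when V-unassignable."""
        v_call, v_aln = self.assign_v(sequence)
        if v_aln is None:
            return None
        regions = self.locate_regions(sequence, v_aln)
        junction = self.locate_junction(sequence, v_aln)

        r = Rearrangement(
            read_id=read_id,
            donor_id=donor_id,
            sequence=sequence,
            v_call=v_call,
            has_indel=v_aln.has_indel,
            v_germ_start=v_aln.germ_start,
            v_germ_end=v_aln.germ_end,
            v_read_start=v_aln.read_start,
        )
        r.region_sequences = {
            k: v for k, v in regions.items() if k in ANALYSIS_REGIONS
        }
        if junction is not None:
            r.j_call = junction["j_call"]
            r.d_call = junction["d_call"]
            r.junction_nt = junction["junction_nt"]
            r.cdr3_aa = junction["cdr3_aa"]
            r.n_nucleotides = junction["n_nucleotides"]
            r.junction_deletions = junction["junction_deletions"]
            r.region_sequences["CDR3"] = junction["cdr3_nt"]
            cdr1_start = v_aln.read_index_of(codon_nt_span(27)[0])
            r.productive = cdr1_start is not None and self.is_productive(
                sequence, cdr1_start, junction
            )
            r.subclass = self.assign_subclass(sequence[junction["junction_end"] :])
        r.complete = junction is not None and all(
            reg in r.region_sequences for reg in ANALYSIS_REGIONS
        )
        r.has_ambiguous_base = scan_ambiguous(r.sequence_key)
        return r

    def annotate_reads(
        self,
        reads: Sequence[RawRead],
        donor_id: Optional[str] = None,
        trim: Optional[tuple[int, int]] = (DEFAULT_TRIM, DEFAULT_TRIM),
    ) -> tuple[list[Rearrangement], int]:
        """Annotate raw reads; returns (rearrangements, n_dropped).

        Donor ids default to the read-id prefix before ``|`` (the simulator's
        convention); reads too short to trim or V-unassignable are dropped
        and counted, never raised.
        """
        out: list[Rearrangement] = []
        dropped = 0
        for raw in reads:
            seq = raw.sequence
            if trim is not None:
                trimmed = trim_flanks(seq, *trim)
                if trimmed is None:
                    dropped += 1
                    continue
                seq = trimmed
            donor = donor_id
            if donor is None:
                donor = raw.read_id.split("|", 1)[0] if "|" in raw.read_id else "unknown"
            rec = self.annotate_read(raw.read_id, donor, seq)
            if rec is None:
                dropped += 1
            else:
                out.append(rec)
        return out, dropped
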