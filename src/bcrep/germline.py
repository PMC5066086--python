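"""Germline reference segments and IMGT-style coordinate conventions.

The package ships a small synthetic toy germline set (10 V, 4 D, 4 J
segments and 6 constant-region subclass motifs) that is generated
deterministically at import time.  The segments are not biological
sequences: they are random coding-frame sequences carrying the structural
anchors the analysis relies on (conserved Cys at codon 104 of V, the J-Trp
anchor of codon 118, no in-frame stop codons).  Segment names borrow real
IGH gene labels so that gene-usage statistics read naturally.  Users with
real data are expected to annotate externally and provide AIRR TSV.

Coordinates follow IMGT unique numbering, 1-based codons, with the V gene
laid out as sequential codons 1..104 plus a short 3' tail that contributes
to the CDR3.  Region boundaries (end codons): FR1 26, CDR1 38, FR2 55,
CDR2 65, FR3 104.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from Bio.Seq import Seq

# IMGT codon boundaries: region -> (first codon, last codon), closed.
FR1_SPAN = (1, 26)
CDR1_SPAN = (27, 38)
FR2_SPAN = (39, 55)
CDR2_SPAN = (56, 65)
FR3_SPAN = (66, 104)

REGION_CODON_SPANS = {
    "FR1": FR1_SPAN,
    "CDR1": CDR1_SPAN,
    "FR2": FR2_SPAN,
    "CDR2": CDR2_SPAN,
    "FR3": FR3_SPAN,
}

#: Regions entering mutation analysis (FR1 is excluded: primer territory;
#: CDR3 is excluded: the germline of N regions is undefined).
ANALYSIS_REGIONS = ("CDR1", "FR2", "CDR2", "FR3")
CDR_REGIONS = frozenset({"CDR1", "CDR2"})
FR_REGIONS = frozenset({"FR2", "FR3"})

V_CODONS = 104
#: Number of V nucleotides past codon 104 that reach into the CDR3.
V_CDR3_TAIL_NT = 6
V_CORE_NT = V_CODONS * 3          # 312
V_TOTAL_NT = V_CORE_NT + V_CDR3_TAIL_NT

#: 1-based nucleotide span of the mutation-analysis window (codons 27-104).
ANALYSIS_NT_SPAN = ((CDR1_SPAN[0] - 1) * 3 + 1, V_CORE_NT)  # (79, 312)

NUCLEOTIDES = "ACGT"
TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
PURINES = frozenset("AG")

#: IGH constant genes in locus order; class switching only moves rightward.
LOCUS_ORDER = ("IGM", "IGD", "IGG3", "IGG1", "IGA1", "IGG2", "IGG4", "IGE", "IGA2")
#: Subclasses distinguishable by the assay's constant-region reverse primers.
SEQUENCED_SUBCLASSES = ("IGG3", "IGG1", "IGA1", "IGG2", "IGG4", "IGA2")
IGG_SUBCLASSES = ("IGG1", "IGG2", "IGG3", "IGG4")
IGA_SUBCLASSES = ("IGA1", "IGA2")

AGE_GROUPS = ("CB", "1-3", "4-10", "11-17", "18-39", "40-74")


def translate(nt: str) -> str:
    """Translate a nucleotide string (length multiple of 3, ACGT only)."""
    return str(Seq(nt).translate())


def codon_nt_span(codon: int) -> tuple[int, int]:
    """1-based closed nucleotide span of an IMGT codon within the V."""
    return (codon - 1) * 3 + 1, codon * 3


def region_of_nt(position: int) -> Optional[str]:
    """Region name for a 1-based V nucleotide position (None outside FR1..FR3)."""
    codon = (position - 1) // 3 + 1
    for region, (lo, hi) in REGION_CODON_SPANS.items():
        if lo <= codon <= hi:
            return region
    return None


def age_group_of(age_years: float, is_cord_blood: bool = False) -> str:
    """Default age binning used throughout the cohort summaries."""
    if is_cord_blood:
        return "CB"
    for group, hi in (("1-3", 3), ("4-10", 10), ("11-17", 17), ("18-39", 39)):
        if age_years <= hi:
            return group
    return "40-74"


@dataclass(frozen=True)
class GermlineSegment:
    """One germline gene segment (V, D or J allele).

    ``v_region_boundaries`` carries the IMGT end codons delimiting
    FR1/CDR1/FR2/CDR2/FR3 and is present exactly for V segments.
    For J segments ``anchor_offset`` is the 0-based offset of the
    conserved Trp (TGG) codon within the segment.
    """

    name: str
    segment_class: str  # "V" | "D" | "J"
    sequence: str
    v_region_boundaries: Optional[tuple[int, ...]] = None
    anchor_offset: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.sequence or self.sequence != self.sequence.upper():
            raise ValueError(f"{self.name}: sequence must be non-empty uppercase")
        if set(self.sequence) - set(NUCLEOTIDES):
            raise ValueError(f"{self.name}: sequence must be A/C/G/T only")
        if self.segment_class not in ("V", "D", "J"):
            raise ValueError(f"{self.name}: bad segment_class {self.segment_class!r}")
        has_bounds = self.v_region_boundaries is not None
        if has_bounds != (self.segment_class == "V"):
            raise ValueError(f"{self.name}: boundaries present iff segment is V")
        if has_bounds and list(self.v_region_boundaries) != sorted(
            set(self.v_region_boundaries)
        ):
            raise ValueError(f"{self.name}: boundaries must be strictly increasing")
        if self.segment_class == "J":
            off = self.anchor_offset
            if off is None or self.sequence[off : off + 3] != "TGG":
                raise ValueError(f"{self.name}: J anchor must point at a TGG codon")

    @property
    def gene(self) -> str:
        """Gene name with the allele suffix stripped (IGHV4-34*01 -> IGHV4-34)."""
        return self.name.split("*")[0]


#: Standard IMGT end codons of FR1/CDR1/FR2/CDR2/FR3.
DEFAULT_V_BOUNDARIES = (26, 38, 55, 65, 104)


@dataclass
class GermlineDatabase:
    """Ordered germline segment collections plus constant-region motifs."""

    v_segments: list[GermlineSegment]
    d_segments: list[GermlineSegment]
    j_segments: list[GermlineSegment]
    subclass_motifs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._by_name = {
            s.name: s for s in self.v_segments + self.d_segments + self.j_segments
        }

    def __getitem__(self, name: str) -> GermlineSegment:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name


_STOP_CODONS = {"TAA", "TAG", "TGA"}


def _random_orf(rng: np.random.Generator, n_codons: int) -> str:
    """Random in-frame sequence without stop codons."""
    codons = []
    while len(codons) < n_codons:
        codon = "".join(rng.choice(list(NUCLEOTIDES), size=3))
        if codon not in _STOP_CODONS:
            codons.append(codon)
    return "".join(codons)


def _make_toy_db() -> GermlineDatabase:
    # Fixed literal seed: the toy set is part of the package contract and
    # must be byte-identical across sessions.
    rng = np.random.default_rng(20161017)

    v_names = [
        "IGHV1-2*01", "IGHV1-69*01", "IGHV2-5*01", "IGHV3-7*01",
        "IGHV3-23*01", "IGHV3-30*01", "IGHV4-34*01", "IGHV4-59*01",
        "IGHV5-51*01", "IGHV6-1*01",
    ]
    v_segments = []
    for name in v_names:
        body = _random_orf(rng, V_CODONS - 1)
        cys = "TGT" if rng.random() < 0.5 else "TGC"
        # Short 3' tail reaching into the CDR3 (codons 105-106 analogue).
        tail = _random_orf(rng, V_CDR3_TAIL_NT // 3)
        v_segments.append(
            GermlineSegment(
                name=name,
                segment_class="V",
                sequence=body + cys + tail,
                v_region_boundaries=DEFAULT_V_BOUNDARIES,
            )
        )

    d_names = ["IGHD2-2*01", "IGHD3-10*01", "IGHD3-22*01", "IGHD6-19*01"]
    d_segments = [
        GermlineSegment(
            name=name,
            segment_class="D",
            sequence="".join(rng.choice(list(NUCLEOTIDES), size=int(length))),
        )
        for name, length in zip(d_names, (18, 24, 21, 15))
    ]

    j_names = ["IGHJ3*01", "IGHJ4*01", "IGHJ5*01", "IGHJ6*01"]
    j_segments = []
    for name, head_len in zip(j_names, (12, 9, 12, 15)):
        head = "".join(rng.choice(list(NUCLEOTIDES), size=int(head_len)))
        fr4 = _random_orf(rng, 10)  # codons 119-128 analogue
        j_segments.append(
            GermlineSegment(
                name=name,
                segment_class="J",
                sequence=head + "TGG" + fr4,
                anchor_offset=int(head_len),
            )
        )

    motifs: dict[str, str] = {}
    taken: set[str] = set()
    for subclass in SEQUENCED_SUBCLASSES:
        while True:
            motif = "".join(rng.choice(list(NUCLEOTIDES), size=15))
            if motif not in taken:
                taken.add(motif)
                motifs[subclass] = motif
                break
    return GermlineDatabase(v_segments, d_segments, j_segments, motifs)


_TOY_DB: Optional[GermlineDatabase] = None


def default_germline_db() -> GermlineDatabase:
    """The packaged synthetic toy germline database (memoized)."""
    global _TOY_DB
    if _TOY_DB is None:
        _TOY_DB = _make_toy_db()
    return _TOY_DB
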