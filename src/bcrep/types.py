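"""Core record types shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .germline import NUCLEOTIDES, age_group_of

SUBCLASSES = ("IGG1", "IGG2", "IGG3", "IGG4", "IGA1", "IGA2")
UNDEFINED = "UNDEFINED"

#: Regions whose read substrings are carried on a Rearrangement.
REARRANGEMENT_REGIONS = ("CDR1", "FR2", "CDR2", "FR3", "CDR3")


@dataclass
class Rearrangement:
    """One annotated IGH transcript.

    V-coordinate bookkeeping (``v_germ_start``/``v_germ_end``/``v_read_start``)
    records the gap-free alignment of the read to its top germline V so that
    mutation calling can map germline positions onto the read; reads whose V
    alignment required gaps are flagged ``has_indel`` and never enter
    mutation analysis.
    """

    read_id: str
    donor_id: str
    sequence: str
    v_call: list[str] = field(default_factory=list)
    j_call: list[str] = field(default_factory=list)
    d_call: list[str] = field(default_factory=list)
    subclass: str = UNDEFINED
    region_sequences: dict[str, str] = field(default_factory=dict)
    junction_nt: str = ""
    cdr3_aa: str = ""
    productive: bool = False
    complete: bool = False
    has_ambiguous_base: bool = False
    duplicate_count: int = 1
    n_nucleotides: int = 0
    junction_deletions: int = 0
    has_indel: bool = False
    # 1-based germline V span covered by the (gap-free) alignment and the
    # 0-based read index where that span starts.
    v_germ_start: int = 0
    v_germ_end: int = 0
    v_read_start: int = 0

    def __post_init__(self) -> None:
        if self.duplicate_count < 1:
            raise ValueError("duplicate_count must be >= 1")

    @property
    def v_gene(self) -> str:
        return self.v_call[0].split("*")[0] if self.v_call else ""

    @property
    def j_gene(self) -> str:
        return self.j_call[0].split("*")[0] if self.j_call else ""

    @property
    def isotype_class(self) -> Optional[str]:
        """IGG / IGA family of the subclass, None when undefined."""
        if self.subclass in SUBCLASSES:
            return self.subclass[:3]
        return None

    @property
    def duplicate_key(self) -> tuple[str, str]:
        """Collapse key: exact CDR1-start..CDR3-end nucleotides + subclass."""
        return self.sequence_key, self.subclass

    @property
    def sequence_key(self) -> str:
        """Exact CDR1..CDR3 nucleotide string (region substrings in order)."""
        return "".join(
            self.region_sequences.get(r, "") for r in REARRANGEMENT_REGIONS
        )

    def read_base_at_v(self, position: int) -> Optional[str]:
        """Read base aligned to 1-based germline V ``position`` (None if uncovered)."""
        if not (self.v_germ_start <= position <= self.v_germ_end):
            return None
        idx = self.v_read_start + (position - self.v_germ_start)
        if idx >= len(self.sequence):
            return None
        return self.sequence[idx]


def scan_ambiguous(segment: str) -> bool:
    """True when a nucleotide outside A/C/G/T occurs in ``segment``."""
    return bool(set(segment) - set(NUCLEOTIDES))


@dataclass(frozen=True)
class DonorMetadata:
    donor_id: str
    age_years: float
    is_cord_blood: bool
    sex: str
    age_group: str = ""

    def __post_init__(self) -> None:
        if self.age_years < 0:
            raise ValueError("age_years must be >= 0")
        expected = age_group_of(self.age_years, self.is_cord_blood)
        if self.age_group == "":
            object.__setattr__(self, "age_group", expected)
        elif self.age_group != expected:
            raise ValueError(
                f"{self.donor_id}: age_group {self.age_group!r} inconsistent "
                f"with age {self.age_years} (expected {expected!r})"
            )
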