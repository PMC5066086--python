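"""Reading and writing the pipeline's interchange formats.

FASTA is read through Biopython; annotated rearrangements travel as AIRR
Rearrangement TSV (tab-separated, UTF-8, header row) using standard AIRR
column names where they exist (``c_call`` for the constant-gene subclass,
``duplicate_count``, per-region ``cdr1``..``fr3`` columns) plus
``bcrep_``-namespaced extension columns for package-specific fields.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from .types import UNDEFINED, DonorMetadata, Rearrangement


class FastaParseError(ValueError):
    pass


class AirrSchemaError(ValueError):
    pass


@dataclass(frozen=True)
class RawRead:
    read_id: str
    sequence: str


def read_fasta(path: str | os.PathLike) -> list[RawRead]:
    """Read a FASTA file into raw reads (uppercased, U normalized to T).

    Raises :class:`FastaParseError` naming the offending line when the file
    does not start with a FASTA header.
    """
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: expected FASTA header '>', got {line.strip()[:30]!r}"
                )
            break
        else:
            return []  # empty file
    reads = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper().replace("U", "T")
        reads.append(RawRead(read_id=record.id, sequence=seq))
    return reads


def write_fasta(reads: Iterable[tuple[str, str]], path: str | os.PathLike) -> None:
    with open(path, "w") as handle:
        for read_id, seq in reads:
            handle.write(f">{read_id}\n{seq}\n")


# --- AIRR Rearrangement TSV ------------------------------------------------

MANDATORY_AIRR_COLUMNS = ("sequence_id", "sequence", "v_call", "j_call", "junction")

_REGION_COLUMNS = {"CDR1": "cdr1", "FR2": "fr2", "CDR2": "cdr2", "FR3": "fr3", "CDR3": "cdr3"}

_BOOL = {"T": True, "F": False, "TRUE": True, "FALSE": False, "": False}


def _fmt_bool(value: bool) -> str:
    return "T" if value else "F"


def write_airr(records: Iterable[Rearrangement], path: str | os.PathLike) -> None:
    """Write rearrangements as AIRR TSV (lossless for all record fields)."""
    rows = []
    for r in records:
        row = {
            "sequence_id": r.read_id,
            "sequence": r.sequence,
            "rev_comp": "F",
            "productive": _fmt_bool(r.productive),
            "v_call": ",".join(r.v_call),
            "d_call": ",".join(r.d_call),
            "j_call": ",".join(r.j_call),
            "c_call": "" if r.subclass == UNDEFINED else r.subclass,
            "junction": r.junction_nt,
            "cdr3_aa": r.cdr3_aa,
            "duplicate_count": r.duplicate_count,
            "bcrep_donor_id": r.donor_id,
            "bcrep_n_nucleotides": r.n_nucleotides,
            "bcrep_junction_deletions": r.junction_deletions,
            "bcrep_has_indel": _fmt_bool(r.has_indel),
            "bcrep_has_ambiguous_base": _fmt_bool(r.has_ambiguous_base),
            "bcrep_complete": _fmt_bool(r.complete),
            "bcrep_v_germ_start": r.v_germ_start,
            "bcrep_v_germ_end": r.v_germ_end,
            "bcrep_v_read_start": r.v_read_start,
        }
        for region, col in _REGION_COLUMNS.items():
            row[col] = r.region_sequences.get(region, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_airr(path: str | os.PathLike) -> list[Rearrangement]:
    """Read an AIRR Rearrangement TSV; extension columns default sensibly.

    Raises :class:`AirrSchemaError` listing any missing mandatory columns.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in MANDATORY_AIRR_COLUMNS if c not in df.columns]
    if missing:
        raise AirrSchemaError(f"{path}: missing mandatory AIRR columns: {missing}")

    def get(row, col, default=""):
        return row[col] if col in df.columns else default

    records = []
    for _, row in df.iterrows():
        regions = {
            region: get(row, col)
            for region, col in _REGION_COLUMNS.items()
            if get(row, col)
        }
        records.append(
            Rearrangement(
                read_id=row["sequence_id"],
                donor_id=get(row, "bcrep_donor_id", "unknown"),
                sequence=row["sequence"],
                v_call=[v for v in row["v_call"].split(",") if v],
                d_call=[d for d in get(row, "d_call").split(",") if d],
                j_call=[j for j in row["j_call"].split(",") if j],
                subclass=get(row, "c_call") or UNDEFINED,
                region_sequences=regions,
                junction_nt=row["junction"],
                cdr3_aa=get(row, "cdr3_aa"),
                productive=_BOOL.get(get(row, "productive").upper(), False),
                complete=_BOOL.get(
                    get(row, "bcrep_complete").upper(),
                    all(r in regions for r in ("CDR1", "FR2", "CDR2", "FR3")),
                ),
                has_ambiguous_base=_BOOL.get(
                    get(row, "bcrep_has_ambiguous_base").upper(), False
                ),
                duplicate_count=int(get(row, "duplicate_count", "1") or 1),
                n_nucleotides=int(get(row, "bcrep_n_nucleotides", "0") or 0),
                junction_deletions=int(get(row, "bcrep_junction_deletions", "0") or 0),
                has_indel=_BOOL.get(get(row, "bcrep_has_indel").upper(), False),
                v_germ_start=int(get(row, "bcrep_v_germ_start", "0") or 0),
                v_germ_end=int(get(row, "bcrep_v_germ_end", "0") or 0),
                v_read_start=int(get(row, "bcrep_v_read_start", "0") or 0),
            )
        )
    return records


# --- Donor metadata --------------------------------------------------------

def read_donor_metadata(path: str | os.PathLike) -> list[DonorMetadata]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["donor_id", "age_years", "is_cord_blood", "sex"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise AirrSchemaError(f"{path}: missing donor metadata columns: {missing}")
    return [
        DonorMetadata(
            donor_id=row["donor_id"],
            age_years=float(row["age_years"]),
            is_cord_blood=_BOOL.get(row["is_cord_blood"].upper(), False),
            sex=row["sex"],
        )
        for _, row in df.iterrows()
    ]


def write_donor_metadata(donors: Iterable[DonorMetadata], path: str | os.PathLike) -> None:
    pd.DataFrame(
        [
            {
                "donor_id": d.donor_id,
                "age_years": d.age_years,
                "is_cord_blood": _fmt_bool(d.is_cord_blood),
                "sex": d.sex,
                "age_group": d.age_group,
            }
            for d in donors
        ]
    ).to_csv(path, sep="\t", index=False)
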