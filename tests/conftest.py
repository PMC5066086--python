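"""Shared fixtures: the packaged toy germline set and small simulated repertoires."""

from __future__ import annotations

import pytest
from hypothesis import settings

from bcrep import (
    Annotator,
    DonorMetadata,
    SimulationConfig,
    Rearrangement,
    default_germline_db,
    emit_repertoire,
)

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def db():
    return default_germline_db()


@pytest.fixture(scope="session")
def annotator():
    return Annotator()


@pytest.fixture(scope="session")
def adult_donor():
    return DonorMetadata(donor_id="DX", age_years=30.0, is_cord_blood=False, sex="F")


@pytest.fixture(scope="session")
def clean_repertoire(adult_donor):
    """Error-free, well-duplicated single-donor repertoire (truth == emitted)."""
    config = SimulationConfig(
        seed=42,
        donors=[adult_donor],
        n_clones=15,
        mutation_rate=0.07,
        sequencing_error_rate=0.0,
        duplicate_depth_min=2,
        min_interclone_distance=8,
    )
    return emit_repertoire(config)


@pytest.fixture(scope="session")
def noisy_repertoire(adult_donor):
    """Single-donor repertoire with sequencing errors and singleton depth."""
    config = SimulationConfig(
        seed=43,
        donors=[adult_donor],
        n_clones=25,
        mutation_rate=0.07,
        sequencing_error_rate=2e-3,
    )
    return emit_repertoire(config)


@pytest.fixture()
def make_transcript(db):
    """Factory for synthetic V-only transcripts with chosen substitutions."""

    def _make(
        mutations: tuple[tuple[int, str], ...] = (),
        v_name: str = "IGHV3-23*01",
        read_id: str = "r0",
        donor_id: str = "d0",
        subclass: str = "IGG1",
    ) -> Rearrangement:
        v = db[v_name]
        seq = list(v.sequence)
        for pos, to_base in mutations:
            if seq[pos - 1] == to_base:  # keep it a substitution
                to_base = "ACGT"[("ACGT".index(to_base) + 1) % 4]
            seq[pos - 1] = to_base
        seq = "".join(seq)
        return Rearrangement(
            read_id=read_id,
            donor_id=donor_id,
            sequence=seq,
            v_call=[v_name],
            j_call=["IGHJ4*01"],
            subclass=subclass,
            region_sequences={
                "CDR1": seq[78:114],
                "FR2": seq[114:165],
                "CDR2": seq[165:195],
                "FR3": seq[195:312],
                "CDR3": seq[312:],
            },
            junction_nt=seq[309:],
            productive=True,
            complete=True,
            v_germ_start=1,
            v_germ_end=len(seq),
            v_read_start=0,
        )

    return _make
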