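"""Germline segments, FASTA/AIRR/metadata IO, and the internal annotator."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st

from bcrep import DonorMetadata, read_airr, write_airr
from bcrep.annotate import Annotator, trim_flanks
from bcrep.germline import (
    ANALYSIS_REGIONS,
    DEFAULT_V_BOUNDARIES,
    GermlineDatabase,
    GermlineSegment,
    codon_nt_span,
    translate,
)
from bcrep.io import AirrSchemaError, FastaParseError, read_fasta
from bcrep.types import Rearrangement, UNDEFINED


class TestGermlineSegment:
    def test_boundaries_only_on_v(self):
        with pytest.raises(ValueError, match="boundaries"):
            GermlineSegment("X*01", "D", "ACGT", v_region_boundaries=(1, 2))
        with pytest.raises(ValueError, match="boundaries"):
            GermlineSegment("X*01", "V", "ACGTAA")

    def test_sequence_validation(self):
        with pytest.raises(ValueError):
            GermlineSegment("X*01", "D", "acgt")
        with pytest.raises(ValueError):
            GermlineSegment("X*01", "D", "ACGN")

    def test_packaged_set_structure(self, db):
        assert len(db.v_segments) == 10
        for v in db.v_segments:
            assert v.v_region_boundaries == DEFAULT_V_BOUNDARIES
            # conserved Cys at codon 104, no stops in the V frame
            lo, hi = codon_nt_span(104)
            assert translate(v.sequence[lo - 1 : hi]) == "C"
            assert "*" not in translate(v.sequence[:312])
        for j in db.j_segments:
            off = j.anchor_offset
            assert j.sequence[off : off + 3] == "TGG"
        assert len(db.subclass_motifs) == 6


class TestFasta:
    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        assert read_fasta(p) == []

    def test_two_entries_and_normalization(self, tmp_path):
        p = tmp_path / "toy.fasta"
        p.write_text(">a\nacgt\n>b\nUUGG\n")
        reads = read_fasta(p)
        assert [r.read_id for r in reads] == ["a", "b"]
        assert reads[0].sequence == "ACGT"
        assert reads[1].sequence == "TTGG"

    def test_malformed_names_line(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text("ACGT\n>a\nACGT\n")
        with pytest.raises(FastaParseError, match="line 1"):
            read_fasta(p)


class TestTrimFlanks:
    def test_zero_trim_is_identity(self):
        assert trim_flanks("ACGTACGT", 0, 0) == "ACGTACGT"

    def test_default_removes_forty_each_side(self):
        seq = "A" * 100
        assert trim_flanks(seq) == "A" * 20

    def test_too_short_read_is_dropped(self):
        assert trim_flanks("A" * 79) is None
        assert trim_flanks("A" * 80) is None  # boundary: nothing would remain


class TestAssignV:
    def test_identity_for_every_packaged_v(self, db, annotator):
        for v in db.v_segments:
            v_call, aln = annotator.assign_v(v.sequence)
            assert v_call[0] == v.name
            assert not aln.has_indel
            assert aln.germ_start == 1 and aln.germ_end == len(v.sequence)

    def test_five_percent_mutations_keep_top_call(self, db, annotator):
        rng = np.random.default_rng(7)
        for v in db.v_segments:
            seq = list(v.sequence)
            for pos in rng.choice(len(seq), size=len(seq) // 20, replace=False):
                seq[pos] = "ACGT"[(("ACGT".index(seq[pos])) + 1) % 4]
            v_call, _ = annotator.assign_v("".join(seq))
            assert v_call[0] == v.name

    def test_tie_preserves_database_order(self, db):
        twin = db.v_segments[0]
        tied_db = GermlineDatabase(
            v_segments=[
                dataclasses.replace(twin, name="IGHV9-1*01"),
                dataclasses.replace(twin, name="IGHV9-1*02"),
            ],
            d_segments=db.d_segments,
            j_segments=db.j_segments,
            subclass_motifs=db.subclass_motifs,
        )
        v_call, _ = Annotator(tied_db).assign_v(twin.sequence)
        assert v_call == ["IGHV9-1*01", "IGHV9-1*02"]

    def test_unrelated_sequence_is_unassignable(self, annotator):
        rng = np.random.default_rng(0)
        junk = "".join(rng.choice(list("ACGT"), size=300))
        v_call, aln = annotator.assign_v(junk)
        assert aln is None and v_call == []


class TestRegions:
    def test_unmutated_v_regions_match_germline_slices(self, db, annotator):
        v = db.v_segments[3]
        _, aln = annotator.assign_v(v.sequence)
        regions = annotator.locate_regions(v.sequence, aln)
        assert regions["CDR1"] == v.sequence[78:114]
        assert regions["FR2"] == v.sequence[114:165]
        assert regions["CDR2"] == v.sequence[165:195]
        assert regions["FR3"] == v.sequence[195:312]

    def test_read_starting_inside_cdr1_is_incomplete(self, db, annotator):
        v = db.v_segments[3]
        read = v.sequence[87:]  # starts at codon 30
        _, aln = annotator.assign_v(read)
        regions = annotator.locate_regions(read, aln)
        assert "CDR1" not in regions
        assert "FR3" in regions

    def test_region_concatenation_reconstructs_read_span(self, annotator, clean_repertoire):
        """CDR1..FR3 region strings tile the V span without gaps or overlaps."""
        checked = 0
        for raw in clean_repertoire.reads[:30]:
            seq = trim_flanks(raw.sequence)
            rec = annotator.annotate_read(raw.read_id, "d", seq)
            if rec is None or rec.has_indel or not rec.complete:
                continue
            _, aln = annotator.assign_v(seq)
            start = aln.read_index_of(79)
            end = aln.read_index_of(312)
            tiled = "".join(rec.region_sequences[r] for r in ANALYSIS_REGIONS)
            assert tiled == seq[start : end + 1]
            checked += 1
        assert checked >= 20


class TestJunction:
    def test_untrimmed_junction_has_no_deletions_or_n(self, db, annotator):
        v, d, j = db.v_segments[4], db.d_segments[0], db.j_segments[1]
        read = v.sequence + d.sequence + j.sequence + db.subclass_motifs["IGG1"] + "ACGTAC"
        _, aln = annotator.assign_v(read)
        junction = annotator.locate_junction(read, aln)
        assert junction is not None
        assert junction["junction_deletions"] == 0
        assert junction["n_nucleotides"] == 0
        assert junction["d_call"] == [d.name]

    def test_trimmed_junction_recovers_truth(self, db, annotator):
        """3 V-trimmed + 4 N + 2 J-trimmed germline bases: deletions 5, N 4."""
        v, d, j = db.v_segments[4], db.d_segments[0], db.j_segments[2]
        # N bases chosen not to chance-extend the trimmed V/J ends
        v_next = v.sequence[-3]
        n_bases = ("C" if v_next != "C" else "A") + "CCA"
        assert d.sequence[-1] != j.sequence[1] and d.sequence[-2:] != j.sequence[:2]
        read = (
            v.sequence[:-3]
            + n_bases
            + d.sequence
            + j.sequence[2:]
            + db.subclass_motifs["IGA2"] + "ACGTAC"
        )
        _, aln = annotator.assign_v(read)
        junction = annotator.locate_junction(read, aln)
        assert junction["junction_deletions"] == 5
        assert junction["n_nucleotides"] == 4
        assert annotator.assign_subclass(read[junction["junction_end"] :]) == "IGA2"

    def test_mutated_cys_anchor_leaves_junction_undefined(self, db, annotator):
        v, d, j = db.v_segments[4], db.d_segments[0], db.j_segments[1]
        read = list(v.sequence + d.sequence + j.sequence)
        read[309:312] = list("GGG")  # destroy Cys-104
        read = "".join(read)
        _, aln = annotator.assign_v(read)
        assert annotator.locate_junction(read, aln) is None


class TestProductivity:
    def test_in_frame_junction_without_stops(self, annotator, db):
        v, d, j = db.v_segments[0], db.d_segments[3], db.j_segments[0]
        read = v.sequence + d.sequence + j.sequence
        _, aln = annotator.assign_v(read)
        junction = annotator.locate_junction(read, aln)
        cdr1_start = aln.read_index_of(79)
        assert len(junction["junction_nt"]) % 3 == 0
        assert annotator.is_productive(read, cdr1_start, junction)

    def test_out_of_frame_junction(self, annotator, db):
        v, d, j = db.v_segments[0], db.d_segments[3], db.j_segments[0]
        read = v.sequence + "A" + d.sequence + j.sequence  # 1-nt frameshift
        _, aln = annotator.assign_v(read)
        junction = annotator.locate_junction(read, aln)
        assert len(junction["junction_nt"]) % 3 != 0
        assert not annotator.is_productive(read, aln.read_index_of(79), junction)

    def test_stop_codon_in_fr3(self, annotator, db):
        v, d, j = db.v_segments[0], db.d_segments[3], db.j_segments[0]
        read = list(v.sequence + d.sequence + j.sequence)
        read[207:210] = list("TAA")  # codon 70, inside FR3
        read = "".join(read)
        _, aln = annotator.assign_v(read)
        junction = annotator.locate_junction(read, aln)
        assert junction is not None
        assert not annotator.is_productive(read, aln.read_index_of(79), junction)

    def test_productivity_invariant_under_silent_mutations(self, annotator, db):
        """Synonymous substitutions never flip the productivity call."""
        from bcrep.shm import classify_rs

        v, d, j = db.v_segments[0], db.d_segments[1], db.j_segments[0]
        base_read = v.sequence + d.sequence + j.sequence
        # precondition: the unmutated read is productive
        _, aln0 = annotator.assign_v(base_read)
        junc0 = annotator.locate_junction(base_read, aln0)
        assert annotator.is_productive(base_read, aln0.read_index_of(79), junc0)
        rng = np.random.default_rng(11)
        for _ in range(25):
            seq = list(base_read)
            n_applied = 0
            while n_applied < 5:
                pos = int(rng.integers(79, 313))  # 1-based within analysis span
                codon_idx = (pos - 1) // 3
                codon = base_read[codon_idx * 3 : codon_idx * 3 + 3]
                to = "ACGT"[int(rng.integers(4))]
                if to == base_read[pos - 1]:
                    continue
                if classify_rs(codon, (pos - 1) % 3 + 1, to) == "S":
                    seq[pos - 1] = to
                    n_applied += 1
            mutated = "".join(seq)
            _, aln = annotator.assign_v(mutated)
            junction = annotator.locate_junction(mutated, aln)
            assert junction is not None
            assert annotator.is_productive(mutated, aln.read_index_of(79), junction)


class TestSubclass:
    def test_single_motif_match(self, db, annotator):
        tail = "ACGT" + db.subclass_motifs["IGG1"] + "ACGT"
        assert annotator.assign_subclass(tail) == "IGG1"

    def test_no_match_is_undefined(self, annotator):
        assert annotator.assign_subclass("ACGT" * 10) == UNDEFINED

    def test_short_tail_is_undefined(self, db, annotator):
        assert annotator.assign_subclass(db.subclass_motifs["IGG1"][:10]) == UNDEFINED

    def test_multiple_matches_are_undefined(self, db, annotator):
        tail = db.subclass_motifs["IGG1"] + db.subclass_motifs["IGA1"]
        assert annotator.assign_subclass(tail) == UNDEFINED

    def test_simulated_subclasses_round_trip(self, annotator, clean_repertoire):
        truth = {t.read_id: t.subclass for t in clean_repertoire.truth}
        # reads whose SHM happened to destroy a junction anchor carry no
        # defined junction and are skipped (they are filtered as incomplete)
        complete = {r.read_id for r in clean_repertoire.rearrangements if r.complete}
        checked = 0
        for raw in clean_repertoire.reads[:30]:
            if raw.read_id not in complete:
                continue
            rec = annotator.annotate_read(raw.read_id, "d", trim_flanks(raw.sequence))
            assert rec.subclass == truth[raw.read_id]
            checked += 1
        assert checked >= 25


class TestAirrIO:
    def test_round_trip_is_lossless(self, tmp_path, clean_repertoire):
        path = tmp_path / "r.tsv"
        records = clean_repertoire.rearrangements[:10]
        write_airr(records, path)
        assert read_airr(path) == records

    @given(
        st.lists(
            st.tuples(
                st.text(alphabet="abc123", min_size=1, max_size=8),
                st.text(alphabet="ACGT", min_size=9, max_size=30),
                st.integers(min_value=1, max_value=99),
                st.booleans(),
            ),
            min_size=1,
            max_size=8,
        )
    )
    def test_round_trip_random_records(self, tmp_path_factory, rows):
        records = [
            Rearrangement(
                read_id=f"{read_id}_{k}",
                donor_id="dX",
                sequence=seq,
                v_call=["IGHV1-2*01"],
                j_call=["IGHJ4*01"],
                junction_nt=seq[:9],
                duplicate_count=dup,
                productive=flag,
                complete=flag,
                has_indel=not flag,
            )
            for k, (read_id, seq, dup, flag) in enumerate(rows)
        ]
        path = tmp_path_factory.mktemp("airr") / "x.tsv"
        write_airr(records, path)
        assert read_airr(path) == records

    def test_missing_junction_column_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("sequence_id\tsequence\tv_call\tj_call\nr1\tACGT\tV\tJ\n")
        with pytest.raises(AirrSchemaError, match="junction"):
            read_airr(path)

    def test_minimal_external_airr_gets_defaults(self, tmp_path):
        path = tmp_path / "min.tsv"
        path.write_text(
            "sequence_id\tsequence\tv_call\tj_call\tjunction\n"
            "r1\tACGTACGTA\tIGHV1-2*01\tIGHJ4*01\tTGTAAATGG\n"
        )
        (rec,) = read_airr(path)
        assert rec.duplicate_count == 1
        assert rec.subclass == UNDEFINED
        assert not rec.complete  # no region columns present


class TestDonorMetadata:
    def test_age_group_derived(self):
        d = DonorMetadata("d1", 8.0, False, "M")
        assert d.age_group == "4-10"

    def test_cord_blood_forces_cb_group(self):
        assert DonorMetadata("d2", 0.0, True, "F").age_group == "CB"

    def test_inconsistent_group_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            DonorMetadata("d3", 50.0, False, "F", age_group="1-3")
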