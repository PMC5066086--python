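"""Junction-distance clone partitioning and minimal-substitution lineage trees."""

from __future__ import annotations

import itertools
import random

import numpy as np
import pytest

from bcrep import DonorMetadata, SimulationConfig, emit_repertoire
from bcrep.clonality import (
    Clone,
    build_lineage_tree,
    clonality_summary,
    junction_hamming,
    partition_clones,
)
from bcrep.filtering import apply_quality_filters


class TestJunctionHamming:
    def test_identical_is_zero(self):
        assert junction_hamming("ACGTACGT", "ACGTACGT") == 0

    def test_single_mismatch(self):
        assert junction_hamming("ACGT", "ACGA") == 1

    def test_ambiguous_base_matches_anything(self):
        """Minimal-distance rule: N versus any base costs nothing."""
        assert junction_hamming("ACNT", "ACGT") == 0
        assert junction_hamming("NNNN", "ACGT") == 0

    def test_unequal_lengths_are_contract_violation(self):
        with pytest.raises(ValueError):
            junction_hamming("ACG", "ACGT")


def _toy_transcript(make_transcript, read_id, junction, subclass="IGG1"):
    t = make_transcript(read_id=read_id, subclass=subclass)
    t.junction_nt = junction
    return t


class TestPartitionClones:
    def test_single_transcript_is_its_own_clone(self, make_transcript):
        clones = partition_clones([_toy_transcript(make_transcript, "r0", "TGTAAATGG")])
        assert len(clones) == 1 and clones[0].n_members == 1

    def test_single_linkage_transitivity(self, make_transcript):
        """A-B=2, B-C=2, A-C=4: one clone under single linkage at threshold 3."""
        a = _toy_transcript(make_transcript, "a", "AAAAAAAAA")
        b = _toy_transcript(make_transcript, "b", "AAAAAAATT")
        c = _toy_transcript(make_transcript, "c", "AAAAATTTT")
        # verify the engineered distance matrix by brute force
        assert junction_hamming(a.junction_nt, b.junction_nt) == 2
        assert junction_hamming(b.junction_nt, c.junction_nt) == 2
        assert junction_hamming(a.junction_nt, c.junction_nt) == 4
        clones = partition_clones([a, b, c])
        assert len(clones) == 1
        assert clones[0].read_ids == ["a", "b", "c"]

    def test_inclusive_threshold_boundary(self, make_transcript):
        a = _toy_transcript(make_transcript, "a", "AAAAAAAAA")
        b = _toy_transcript(make_transcript, "b", "AAAAAAttt".upper())
        assert junction_hamming(a.junction_nt, b.junction_nt) == 3
        assert len(partition_clones([a, b], max_distance=3)) == 1
        assert len(partition_clones([a, b], max_distance=2)) == 2

    def test_partition_is_permutation_invariant(self, clean_repertoire):
        unique, _ = apply_quality_filters(clean_repertoire.rearrangements)
        clones = partition_clones(unique)
        shuffled = list(unique)
        random.Random(3).shuffle(shuffled)
        clones_shuffled = partition_clones(shuffled)
        assert [c.read_ids for c in clones] == [c.read_ids for c in clones_shuffled]
        # it is a partition
        all_ids = sorted(itertools.chain.from_iterable(c.read_ids for c in clones))
        assert all_ids == sorted(r.read_id for r in unique if r.junction_nt)

    def test_raising_distance_never_increases_clone_count(self, clean_repertoire):
        unique, _ = apply_quality_filters(clean_repertoire.rearrangements)
        counts = [
            len(partition_clones(unique, max_distance=d)) for d in (0, 1, 3, 6, 10)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_recovers_simulated_clones_exactly(self, adult_donor):
        """Separated clones with small intra-clone junction divergence: ARI = 1."""
        from sklearn.metrics import adjusted_rand_score

        config = SimulationConfig(
            seed=51, donors=[adult_donor], n_clones=20, mutation_rate=0.07,
            sequencing_error_rate=0.0, duplicate_depth_min=2,
            member_junction_snp_mean=0.5, member_junction_snp_cap=1,
            min_interclone_distance=8,
        )
        rep = emit_repertoire(config)
        unique, _ = apply_quality_filters(rep.rearrangements)
        clones = partition_clones(unique)
        truth_of = {t.read_id: t.clone_id for t in rep.truth}
        labels_true, labels_pred = [], []
        for k, clone in enumerate(clones):
            for rid in clone.read_ids:
                labels_true.append(truth_of[rid])
                labels_pred.append(k)
        assert adjusted_rand_score(labels_true, labels_pred) == 1.0


class TestClonalitySummary:
    def test_singleton_clones(self, make_transcript):
        clones = [
            Clone(f"c{i}", [f"r{i}"], "IGHV1-2", "IGHJ4", 9, ["IGG1"]) for i in range(4)
        ]
        s = clonality_summary(clones)
        assert s.max_clone_pct == pytest.approx(25.0)
        assert s.pct_unique_clones == pytest.approx(100.0)

    def test_arithmetic(self):
        clones = [
            Clone("c0", [f"r{i}" for i in range(5)], "V", "J", 9, ["IGG1"]),
            Clone("c1", [f"s{i}" for i in range(5)], "V", "J", 9, ["IGG1"]),
        ]
        s = clonality_summary(clones)
        assert s.max_clone_pct == pytest.approx(50.0)
        assert s.pct_unique_clones == 0.0

    def test_simulated_summary_matches_truth(self, clean_repertoire):
        unique, _ = apply_quality_filters(clean_repertoire.rearrangements)
        clones = partition_clones(unique)
        truth_of = {t.read_id: t.clone_id for t in clean_repertoire.truth}
        sizes: dict[str, int] = {}
        for r in unique:
            sizes[truth_of[r.read_id]] = sizes.get(truth_of[r.read_id], 0) + 1
        s = clonality_summary(clones)
        assert s.max_clone_pct == pytest.approx(100 * max(sizes.values()) / len(unique))
        n_singleton = sum(1 for v in sizes.values() if v == 1)
        assert s.pct_unique_clones == pytest.approx(100 * n_singleton / len(unique))


class TestLineageTrees:
    def _clone_of(self, transcripts):
        return Clone(
            "cX",
            [t.read_id for t in transcripts],
            transcripts[0].v_gene,
            transcripts[0].j_gene,
            len(transcripts[0].junction_nt),
            sorted({t.subclass for t in transcripts}),
        )

    def test_single_member_edge_length_equals_mutation_count(self, db, make_transcript):
        t = make_transcript(mutations=((100, "A"), (150, "C"), (200, "G")))
        tree = build_lineage_tree(self._clone_of([t]), {t.read_id: t}, db)
        assert tree.total_substitutions == 3
        (edge,) = tree.root.children
        assert edge.length == 3 and edge.child.read_ids == ["r0"]

    def test_worked_three_member_example(self, db, make_transcript):
        """Shared {1,2} + privates {3},{4},{5}: one inferred intermediate, total 5."""
        shared = ((100, "A"), (150, "C"))
        members = [
            make_transcript(mutations=shared + ((200, "G"),), read_id="m0"),
            make_transcript(mutations=shared + ((210, "G"),), read_id="m1"),
            make_transcript(mutations=shared + ((220, "G"),), read_id="m2"),
        ]
        tree = build_lineage_tree(
            self._clone_of(members), {t.read_id: t for t in members}, db
        )
        assert tree.exact
        assert tree.total_substitutions == 5
        inferred = [n for n in tree.nodes() if n.is_inferred]
        assert len(inferred) == 1
        assert len(inferred[0].mutations) == 2  # the shared trunk

    def test_conflicting_v_assignment_raises(self, db, make_transcript):
        a = make_transcript(read_id="a", v_name="IGHV1-2*01")
        b = make_transcript(read_id="b", v_name="IGHV3-23*01")
        clone = self._clone_of([a, b])
        with pytest.raises(ValueError, match="cX"):
            build_lineage_tree(clone, {"a": a, "b": b}, db)

    def test_total_bounded_by_member_sum(self, db, clean_repertoire):
        unique, _ = apply_quality_filters(clean_repertoire.rearrangements)
        clones = partition_clones(unique)
        by_read = {r.read_id: r for r in unique}
        from bcrep.shm import mutation_scan

        for clone in clones:
            if clone.n_members < 2:
                continue
            tree = build_lineage_tree(clone, by_read, db)
            member_sum = sum(
                len(mutation_scan(by_read[rid], db[by_read[rid].v_call[0]])[0])
                for rid in clone.read_ids
            )
            assert tree.total_substitutions <= member_sum
            # root-to-leaf mutation unions reproduce each member's called set
            def walk(node, acc):
                acc = acc | node.mutations
                for rid in node.read_ids:
                    muts, _ = mutation_scan(by_read[rid], db[by_read[rid].v_call[0]])
                    assert {(m.position, m.from_base, m.to_base) for m in muts} == acc
                for e in node.children:
                    walk(e.child, acc)

            walk(tree.root, frozenset())

    def test_heuristic_equals_exact_for_small_clones(self, db, adult_donor):
        """Greedy shared-mutation agglomeration matches exhaustive parsimony
        on simulated (homoplasy-free) clones of up to 5 members."""
        config = SimulationConfig(
            seed=53, donors=[adult_donor], n_clones=60, max_clone_size=5,
            mutation_rate=0.05, sequencing_error_rate=0.0, duplicate_depth_min=2,
        )
        rep = emit_repertoire(config)
        unique, _ = apply_quality_filters(rep.rearrangements)
        clones = partition_clones(unique)
        by_read = {r.read_id: r for r in unique}
        n_multi = 0
        for clone in clones:
            exact = build_lineage_tree(clone, by_read, db, exact_limit=8)
            greedy = build_lineage_tree(clone, by_read, db, exact_limit=0)
            assert greedy.total_substitutions == exact.total_substitutions
            n_multi += clone.n_members > 1
        assert n_multi >= 10

    def test_simulated_lineage_recovers_true_substitution_count(self, db, clean_repertoire):
        """Without homoplasy, the parsimony total equals the number of
        distinct true mutations in the clone."""
        unique, _ = apply_quality_filters(clean_repertoire.rearrangements)
        clones = partition_clones(unique)
        by_read = {r.read_id: r for r in unique}
        truth = {t.read_id: t for t in clean_repertoire.truth}
        checked = 0
        for clone in clones:
            if not (2 <= clone.n_members <= 8):
                continue
            true_sets = [set(truth[rid].mutations) for rid in clone.read_ids]
            from bcrep.shm import mutation_scan

            called_ok = all(
                {(m.position, m.from_base, m.to_base)
                 for m in mutation_scan(by_read[rid], db[by_read[rid].v_call[0]])[0]}
                == set(truth[rid].mutations)
                for rid in clone.read_ids
            )
            if not called_ok:
                continue
            tree = build_lineage_tree(clone, by_read, db)
            assert tree.total_substitutions == len(set().union(*true_sets))
            checked += 1
        assert checked >= 3

    def test_newick_export_parses(self, db, clean_repertoire, tmp_path):
        import dendropy

        unique, _ = apply_quality_filters(clean_repertoire.rearrangements)
        clones = [c for c in partition_clones(unique) if c.n_members >= 3]
        by_read = {r.read_id: r for r in unique}
        tree = build_lineage_tree(clones[0], by_read, db)
        newick = tree.to_newick()
        parsed = dendropy.Tree.get(data=newick, schema="newick")
        assert len(parsed.leaf_nodes()) >= 1
        total = sum(
            e.length for e in parsed.preorder_edge_iter() if e.length is not None
        )
        assert total == tree.total_substitutions
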