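"""Sequence curation, distances, NJ trees, conservation grading, mapping."""

import dendropy
import numpy as np
import pytest
from Bio.Phylo.TreeConstruction import DistanceMatrix as BioDM
from Bio.Phylo.TreeConstruction import DistanceTreeConstructor

from pocketcons import seqcons, synthdata
from pocketcons.seqcons import (DistanceMatrix, MultipleAlignment,
                                SequenceError, SequenceRecord,
                                build_nj_tree, filter_length_outliers,
                                map_to_structure, pairwise_distance,
                                score_conservation, select_representatives,
                                assign_grades)


def seq(i, n, organism="org"):
    return SequenceRecord(id=f"s{i}", organism=organism, residues="A" * n)


class TestCuration:
    @pytest.mark.parametrize("lengths, expected_kept", [
        ((100, 95, 61, 59), (100, 95, 61, 59)),    # cutoff 47.25
        ((100, 100, 100, 59), (100, 100, 100, 59)),  # cutoff 53.85
        ((100, 100, 100, 40), (100, 100, 100)),      # 40 < 51
        ((80,), (80,)),                              # single sequence kept
    ])
    def test_length_outlier_cutoff(self, lengths, expected_kept):
        seqs = [seq(i, n) for i, n in enumerate(lengths)]
        kept = filter_length_outliers(seqs, fraction=0.6)
        assert tuple(len(s.ungapped) for s in kept) == expected_kept

    def test_empty_input_rejected(self):
        with pytest.raises(SequenceError):
            filter_length_outliers([])

    def test_one_representative_per_organism(self):
        seqs = [seq(i, 50 + i, organism=f"org{i % 3}") for i in range(5)]
        reps = select_representatives(seqs)
        assert len(reps) == 3
        assert len({r.organism for r in reps}) == 3

    def test_representative_ties_resolved_deterministically(self):
        a = SequenceRecord("idB", "x", "A" * 30)
        b = SequenceRecord("idA", "x", "A" * 30)
        c = SequenceRecord("idC", "x", "A" * 20)
        assert select_representatives([a, b, c])[0].id == "idA"

    def test_missing_organism_named_in_error(self):
        with pytest.raises(SequenceError, match="s0"):
            select_representatives([SequenceRecord("s0", "", "AAA")])


class TestDistances:
    def test_identical_rows_have_zero_distance(self):
        aln = MultipleAlignment([SequenceRecord("a", residues="ACDEF"),
                                 SequenceRecord("b", residues="ACDEF")])
        d = pairwise_distance(aln)
        assert d.values[0, 1] == pytest.approx(0.0)

    def test_worst_pairing_has_distance_one(self):
        # B(A,W) = -3 is the worst score alanine can achieve
        aln = MultipleAlignment([SequenceRecord("a", residues="A"),
                                 SequenceRecord("b", residues="W")])
        assert pairwise_distance(aln).values[0, 1] == pytest.approx(1.0)

    def test_matrix_symmetric_zero_diagonal(self, rate_class_alignment):
        aln, _ = rate_class_alignment
        d = pairwise_distance(aln)
        np.testing.assert_allclose(d.values, d.values.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(d.values), 0.0)

    def test_gap_only_overlap_rejected(self):
        aln = MultipleAlignment([SequenceRecord("a", residues="A-"),
                                 SequenceRecord("b", residues="-W")])
        with pytest.raises(SequenceError):
            pairwise_distance(aln)


def _additive_matrix():
    """Distances on the tree ((A:1,B:2):1,(C:3,D:4))."""
    labels = ["A", "B", "C", "D"]
    d = {("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 6,
         ("B", "C"): 6, ("B", "D"): 7, ("C", "D"): 7}
    m = np.zeros((4, 4))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                m[i, j] = m[j, i] = d[(a, b)]
    return labels, m


class TestNeighborJoining:
    def test_recovers_additive_tree_with_exact_lengths(self):
        labels, m = _additive_matrix()
        tree = build_nj_tree(DistanceMatrix(labels, m))
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(m[i, j])

    def test_three_taxa_single_internal_node(self):
        m = np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], float)
        tree = build_nj_tree(DistanceMatrix(["a", "b", "c"], m))
        assert len(tree.leaf_nodes()) == 3
        internal = [n for n in tree if not n.is_leaf()]
        assert len(internal) == 1

    def test_label_order_invariant_topology(self):
        labels, m = _additive_matrix()
        t1 = build_nj_tree(DistanceMatrix(labels, m))
        perm = [2, 0, 3, 1]
        t2 = build_nj_tree(DistanceMatrix([labels[i] for i in perm],
                                          m[np.ix_(perm, perm)]))
        assert _rf_distance(t1, t2) == 0

    @pytest.mark.parametrize("n_taxa, seed", [(4, 0), (5, 1), (6, 2), (8, 3)])
    def test_matches_independent_nj_oracle(self, n_taxa, seed):
        """Random additive matrices: same topology as Biopython's NJ."""
        rng = np.random.default_rng(seed)
        tree = synthdata.balanced_tree(n_taxa, 1.0, seed=seed)
        for e in tree.preorder_edge_iter():
            if e.length is not None:
                e.length = float(rng.uniform(0.5, 3.0))
        pdm = tree.phylogenetic_distance_matrix()
        taxa = list(tree.taxon_namespace)
        labels = [t.label for t in taxa]
        m = np.array([[pdm.distance(a, b) for b in taxa] for a in taxa])
        ours = build_nj_tree(DistanceMatrix(labels, m))
        bio_dm = BioDM(labels, [[float(m[i, j]) for j in range(i + 1)]
                                for i in range(len(labels))])
        bio_tree = DistanceTreeConstructor().nj(bio_dm)
        oracle = dendropy.Tree.get(data=bio_tree.format("newick"),
                                   schema="newick",
                                   taxon_namespace=ours.taxon_namespace)
        assert _rf_distance(ours, oracle) == 0
        # and both equal the generating topology
        gen = dendropy.Tree.get(data=tree.as_string(schema="newick"),
                                schema="newick",
                                taxon_namespace=ours.taxon_namespace)
        assert _rf_distance(ours, gen) == 0


def _rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    ns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(data=t1.as_string(schema="newick"), schema="newick",
                          taxon_namespace=ns)
    b = dendropy.Tree.get(data=t2.as_string(schema="newick"), schema="newick",
                          taxon_namespace=ns)
    a.encode_bipartitions()
    b.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(a, b)


class TestConservation:
    def test_invariant_column_scores_highest(self):
        rows = [SequenceRecord(f"r{i}", residues=s)
                for i, s in enumerate(["AWKL", "AFRI", "AWKV"])]
        prof = score_conservation(MultipleAlignment(rows))
        assert np.nanargmax(prof.scores) == 0

    def test_slow_columns_outscore_fast(self, scored_profile):
        prof, truth = scored_profile
        slow = truth["class_index"] == 0
        assert np.nanmean(prof.scores[slow]) > np.nanmean(prof.scores[~slow])

    def test_duplicate_sequence_barely_moves_scores(self, rate_class_alignment):
        aln, _ = rate_class_alignment
        base_tree = build_nj_tree(pairwise_distance(aln))
        base = score_conservation(aln, base_tree)
        dup = SequenceRecord("dup0", "duporg", aln.rows[0].residues)
        aln2 = MultipleAlignment(aln.rows + [dup])
        tree2 = build_nj_tree(pairwise_distance(aln2))
        prof2 = score_conservation(aln2, tree2)
        ok = ~base.flags & ~prof2.flags
        assert np.nanmax(np.abs(base.scores[ok] - prof2.scores[ok])) < 0.25

    def test_standardisation(self, scored_profile):
        prof, _ = scored_profile
        ok = ~prof.flags
        assert abs(np.nanmean(prof.scores[ok])) < 1e-9
        assert abs(np.nanstd(prof.scores[ok]) - 1.0) < 1e-9

    def test_gap_dominated_column_flagged_grade_one(self):
        rows = [SequenceRecord("a", residues="A-AA"), SequenceRecord("b", residues="A-AA"),
                SequenceRecord("c", residues="A-AA"), SequenceRecord("d", residues="AWAA")]
        prof = assign_grades(score_conservation(MultipleAlignment(rows)))
        assert prof.flags[1]
        assert prof.grades[1] == 1


class TestGrades:
    def test_fully_conserved_alignment_all_grade_nine(self):
        rows = [SequenceRecord(f"r{i}", residues="ACDEFG") for i in range(4)]
        prof = assign_grades(score_conservation(MultipleAlignment(rows)))
        assert (prof.grades == 9).all()

    def test_wide_rate_alignment_uses_all_nine_grades(self, scored_profile):
        prof, _ = scored_profile
        assert set(range(1, 10)) <= set(int(g) for g in prof.grades)

    def test_grades_monotone_in_score(self, scored_profile):
        prof, _ = scored_profile
        ok = ~prof.flags
        order = np.argsort(prof.scores[ok])
        assert (np.diff(prof.grades[ok][order]) >= 0).all()
        assert set(prof.grades) <= set(range(1, 10))


class TestMapping:
    @pytest.fixture()
    def graded_profile_and_structure(self, cavity_structure):
        seq0 = "".join(r.one_letter for r in cavity_structure.residues)
        rows = [SequenceRecord("anchor", residues=seq0)]
        rng = np.random.default_rng(0)
        for k in range(3):
            mutated = list(seq0)
            for i in rng.choice(len(seq0), size=10, replace=False):
                mutated[i] = "ARNDCQEGHILKMFPSTWYV"[rng.integers(20)]
            rows.append(SequenceRecord(f"h{k}", residues="".join(mutated)))
        prof = assign_grades(score_conservation(MultipleAlignment(rows)))
        return prof, rows[0], cavity_structure

    def test_identical_sequence_maps_every_residue(self, graded_profile_and_structure):
        prof, row, structure = graded_profile_and_structure
        rmap = map_to_structure(prof, row, structure)
        assert not rmap.ungraded
        assert len(rmap.pairs) == len(structure)
        for col, resnum in rmap.pairs:
            assert rmap.grades[resnum] == prof.grades[col]

    def test_truncated_structure_leaves_tail_unmapped(self, graded_profile_and_structure):
        from pocketcons.structio import Structure

        prof, row, structure = graded_profile_and_structure
        trunc = Structure(structure.chain_id, structure.residues[5:])
        rmap = map_to_structure(prof, row, trunc)
        assert len(rmap.pairs) == len(structure) - 5
        mapped_cols = {c for c, _ in rmap.pairs}
        assert mapped_cols == set(range(5, len(structure)))

    def test_unrelated_sequence_rejected(self, graded_profile_and_structure):
        prof, row, structure = graded_profile_and_structure
        decoy = SequenceRecord("decoy", residues="W" * len(row.residues))
        with pytest.raises(SequenceError, match="identity"):
            map_to_structure(prof, decoy, structure)
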