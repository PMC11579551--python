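"""Star MSA, JC distances, Neighbor-Joining, Robinson-Foulds and logos."""

import io
import math

import numpy as np
import pytest

from mtminer.errors import ValidationError
from mtminer.phylo import (
    LOG2_20,
    DistanceMatrix,
    PhyloTree,
    build_logo,
    jc_distance,
    msa_distance_matrix,
    nj_tree,
    p_distance,
    robinson_foulds,
    star_msa,
)
from mtminer.synth import random_additive_tree, synth_mt_variant


class TestStarMSA:
    def test_identical_copies_of_reference_align_without_gaps(self, ref):
        msa = star_msa([("a", ref.sequence), ("b", ref.sequence)], ref)
        assert all("-" not in row for row in msa.rows)

    def test_member_insertion_opens_gap_block_in_other_rows(self, ref):
        k = 100
        with_insert = ref.sequence[:k] + "WWWWW" + ref.sequence[k:]
        msa = star_msa([("ins", with_insert), ("plain", ref.sequence)], ref)
        assert msa.n_columns == len(ref.sequence) + 5
        assert "-" * 5 in msa.rows[0]  # reference row
        assert "-" * 5 in msa.rows[2]  # plain member

    def test_degapping_reproduces_inputs(self, ref):
        members = [
            ("v1", synth_mt_variant(ref, "LFVYINTNHEMWVFLWQ", 0.1, seed=1)[0]),
            ("v2", synth_mt_variant(ref, "LFVYINTNHEEWVFLWQ", 0.1, seed=2)[0]),
        ]
        msa = star_msa(members, ref)
        assert msa.degap(0) == ref.sequence
        for (name, seq), i in zip(members, range(1, 3)):
            assert msa.degap(i) == seq

    def test_fewer_than_two_members_rejected(self, ref):
        with pytest.raises(ValidationError):
            star_msa([("only", ref.sequence)], ref)


class TestDistances:
    def test_identical_rows_have_zero_p_distance(self, ref):
        msa = star_msa([("a", ref.sequence), ("b", ref.sequence)], ref)
        assert p_distance(msa, 1, 2) == 0.0

    def test_p_distance_counts_differing_shared_columns(self):
        from mtminer.phylo import StarMSA

        msa = StarMSA(["r", "a", "b"], ["AAAAAAAAAA", "AAAAAAAAAA", "CAAAAAAAAA"])
        assert p_distance(msa, 1, 2) == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", range(5))
    def test_p_distance_matches_exhaustive_column_count(self, seed):
        from mtminer.phylo import StarMSA

        rng = np.random.default_rng(seed)
        alphabet = list("ACDEFG-")
        rows = ["".join(rng.choice(alphabet, 60)) for _ in range(2)]
        msa = StarMSA(["x", "y"], rows)
        shared = [(a, b) for a, b in zip(*rows) if a != "-" and b != "-"]
        expected = sum(a != b for a, b in shared) / len(shared)
        assert p_distance(msa, 0, 1) == pytest.approx(expected)

    def test_jc_zero_at_zero(self):
        assert jc_distance(0.0) == 0.0

    def test_jc_closed_form_at_half(self):
        # d = -(19/20) ln(1 - (20/19) * 0.5)
        assert jc_distance(0.5) == pytest.approx(0.70985, abs=1e-4)

    def test_jc_dominates_p_and_is_monotone(self):
        ps = np.linspace(0.0, 0.94, 100)
        ds = [jc_distance(p) for p in ps]
        assert all(d >= p for p, d in zip(ps, ds))
        assert all(b > a for a, b in zip(ds, ds[1:]))

    def test_jc_first_order_agreement_for_small_p(self):
        for p in np.linspace(0.001, 0.05, 20):
            assert abs(jc_distance(p) - p) <= p * p

    def test_jc_saturates_to_cap(self):
        assert jc_distance(0.97, cap=10.0) == 10.0

    def test_jc_rejects_invalid_p(self):
        with pytest.raises(ValidationError):
            jc_distance(1.5)


class TestNeighborJoining:
    def test_two_taxa_joined_by_single_edge_of_their_distance(self):
        D = DistanceMatrix(["A", "B"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        tree = nj_tree(D)
        assert tree.leaf_path_length("A", "B") == pytest.approx(1.0)

    def test_additive_four_taxon_matrix_reconstructed_exactly(self):
        # tree: ((A:2,B:3):1,(C:4,D:5)) -> additive distances
        D = DistanceMatrix(
            ["A", "B", "C", "D"],
            np.array(
                [
                    [0, 5, 7, 8],
                    [5, 0, 8, 9],
                    [7, 8, 0, 9],
                    [8, 9, 9, 0],
                ],
                dtype=float,
            ),
        )
        tree = nj_tree(D)
        for i, a in enumerate(D.names):
            for j, b in enumerate(D.names):
                if i < j:
                    assert tree.leaf_path_length(a, b) == pytest.approx(D.data[i, j])
        # AB | CD split present
        from mtminer.phylo import _bipartitions

        assert _bipartitions(tree) == {frozenset({"C", "D"})}

    def test_ultrametric_three_taxon_closest_pair_are_siblings(self):
        D = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, 0.2, 1.0], [0.2, 0, 1.0], [1.0, 1.0, 0]]),
        )
        tree = nj_tree(D)
        # brute force over the 3 rooted pairings: A,B must share the shortest path
        ab = tree.leaf_path_length("A", "B")
        assert ab < tree.leaf_path_length("A", "C")
        assert ab < tree.leaf_path_length("B", "C")

    @pytest.mark.parametrize("seed", range(10))
    def test_random_additive_trees_recovered(self, seed):
        n = 4 + seed % 5  # 4..8 leaves
        D, truth = random_additive_tree(n, seed=seed)
        tree = nj_tree(D)
        assert robinson_foulds(tree, truth) == 0
        for a in D.names:
            for b in D.names:
                if a < b:
                    i, j = D.names.index(a), D.names.index(b)
                    assert tree.leaf_path_length(a, b) == pytest.approx(D.data[i, j])

    @pytest.mark.parametrize("seed", [100, 101, 102])
    def test_agrees_with_scikit_bio_topology(self, seed):
        import skbio

        D, _ = random_additive_tree(7, seed=seed)
        ours = nj_tree(D)
        theirs = skbio.tree.nj(skbio.DistanceMatrix(D.data, ids=D.names))
        assert robinson_foulds(ours, PhyloTree(theirs)) == 0

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValidationError):
            DistanceMatrix(["A", "B"], np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestRobinsonFoulds:
    def test_tree_vs_itself_is_zero(self):
        D, truth = random_additive_tree(6, seed=1)
        assert robinson_foulds(truth, truth) == 0

    def test_distinct_four_leaf_topologies_differ_by_two(self):
        t1 = PhyloTree.read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = PhyloTree.read_newick("((A:1,C:1):1,(B:1,D:1):1);")
        assert robinson_foulds(t1, t2) == 2
        assert robinson_foulds(t2, t1) == 2

    def test_leaf_set_mismatch_rejected(self):
        t1 = PhyloTree.read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = PhyloTree.read_newick("((A:1,B:1):1,(C:1,E:1):1);")
        with pytest.raises(ValidationError):
            robinson_foulds(t1, t2)

    def test_dendropy_agrees_on_random_tree_pairs(self):
        import dendropy

        for seed in (7, 8):
            D1, t1 = random_additive_tree(7, seed=seed)
            D2, t2 = random_additive_tree(7, seed=seed + 50)
            ours = robinson_foulds(t1, t2)
            taxa = dendropy.TaxonNamespace()
            d1 = dendropy.Tree.get(
                data=t1.write_newick(), schema="newick", taxon_namespace=taxa
            )
            d2 = dendropy.Tree.get(
                data=t2.write_newick(), schema="newick", taxon_namespace=taxa
            )
            d1.encode_bipartitions()
            d2.encode_bipartitions()
            theirs = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
            assert ours == theirs


class TestNewickRoundTrip:
    @pytest.mark.parametrize("seed", [3, 4])
    def test_roundtrip_preserves_topology_and_lengths(self, seed):
        D, truth = random_additive_tree(6, seed=seed)
        tree = nj_tree(D)
        again = PhyloTree.read_newick(tree.write_newick())
        assert robinson_foulds(tree, again) == 0
        for a in D.names:
            for b in D.names:
                if a < b:
                    assert again.leaf_path_length(a, b) == pytest.approx(
                        tree.leaf_path_length(a, b), abs=1e-9
                    )


class TestLogos:
    def test_invariant_column_has_full_information(self):
        logo = build_logo(["A", "A", "A", "A"])
        assert logo.information[0] == pytest.approx(math.log2(20))

    def test_uniform_column_has_zero_information(self):
        logo = build_logo([aa for aa in "ACDEFGHIKLMNPQRSTVWY"])
        assert logo.information[0] == pytest.approx(0.0)

    def test_frequencies_normalized_and_ic_bounded_on_random_input(self):
        rng = np.random.default_rng(0)
        strings = [
            "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY-"), 17)) for _ in range(30)
        ]
        logo = build_logo(strings, correct_small_sample=True)
        covered = logo.sample_sizes > 0
        assert np.allclose(logo.frequencies[covered].sum(axis=1), 1.0)
        assert np.all(logo.information >= 0.0)
        assert np.all(logo.information <= LOG2_20 + 1e-12)

    def test_small_sample_correction_lowers_information(self):
        plain = build_logo(["AC", "AC", "AC"], correct_small_sample=False)
        corrected = build_logo(["AC", "AC", "AC"], correct_small_sample=True)
        assert corrected.information[0] < plain.information[0]

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            build_logo([])
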