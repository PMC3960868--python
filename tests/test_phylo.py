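"""Implicit MSA, p-distances, neighbor joining, rooting, Newick I/O."""

import numpy as np
import pytest
import dendropy

from famscan.core_seq import SeqRecord
from famscan.profile_hmm import build_profile, best_hit, DomainHit
from famscan.phylo import (
    TreeError, implicit_msa, p_distance_matrix, nj_tree, midpoint_root,
    parse_newick, newick_string, read_newick, write_newick,
)
from oracles import random_additive_instance


def prot(s, i=0):
    return SeqRecord(id=f"p{i}", residues=s, alphabet="protein")


def arow(rid, s):
    return SeqRecord(id=rid, residues=s, alphabet="protein")


def _patristic(tree):
    pdm = tree.dtree.phylogenetic_distance_matrix()
    taxa = sorted(tree.dtree.taxon_namespace, key=lambda t: t.label)
    out = {}
    for i, a in enumerate(taxa):
        for b in taxa[i + 1:]:
            out[(a.label, b.label)] = pdm.patristic_distance(a, b)
    return out


class TestImplicitMsa:
    def test_consensus_is_ungapped_row(self):
        hmm = build_profile([prot("MKVLAW", i) for i in range(3)])
        hit = best_hit(hmm, prot("MKVLAW", 9))
        rows = implicit_msa(hmm, [hit], {"p9": "MKVLAW"})
        assert rows[0].residues == "MKVLAW"

    def test_delete_state_becomes_gap(self):
        hmm = build_profile([prot("MKVLAW", i) for i in range(3)])
        hit = DomainHit(target_id="q", target_start=0, target_end=5,
                        bit_score=10.0, matched_states=(0, 5), path="MMMDMM")
        rows = implicit_msa(hmm, [hit], {"q": "MKVAW"})
        assert rows[0].residues == "MKV-AW".replace("V-", "V-")
        assert rows[0].residues[3] == "-"

    def test_insert_residues_dropped_rows_equal_length(self):
        hmm = build_profile([prot("MKVLAW", i) for i in range(3)])
        hits = [best_hit(hmm, prot("MKVLAW", 1)),
                DomainHit(target_id="q", target_start=0, target_end=7,
                          bit_score=5.0, matched_states=(0, 5), path="MMMIIMMM"[:8])]
        # path MMMIIMMM: 6 matches + 2 inserts over 8 residues
        rows = implicit_msa(hmm, hits, {"p1": "MKVLAW", "q": "MKVCCLAW"[:8]})
        assert all(len(r.residues) == hmm.K for r in rows)

    def test_missing_path_rejected(self):
        hmm = build_profile([prot("MKVLAW", i) for i in range(3)])
        hit = DomainHit(target_id="q", target_start=0, target_end=6,
                        bit_score=5.0, matched_states=(0, 5), path=None)
        with pytest.raises(TreeError):
            implicit_msa(hmm, [hit], {"q": "MKVLAW"})


class TestPDistance:
    def test_identical_rows_zero(self):
        D, _ = p_distance_matrix([arow("a", "MKVL"), arow("b", "MKVL")])
        assert D[0, 1] == 0.0

    def test_all_different_one(self):
        D, _ = p_distance_matrix([arow("a", "MKVL"), arow("b", "WDEA")])
        assert D[0, 1] == 1.0

    def test_half_mismatches(self):
        D, _ = p_distance_matrix([arow("a", "MKVLAWDEMK"),
                                  arow("b", "MKVLAAAAAA")])
        assert D[0, 1] == 0.5

    def test_gaps_excluded_from_comparison(self):
        D, _ = p_distance_matrix([arow("a", "MK--"), arow("b", "MKVL")])
        assert D[0, 1] == 0.0

    def test_no_comparable_columns_rejected(self):
        with pytest.raises(TreeError, match="a.*b|b.*a"):
            p_distance_matrix([arow("a", "MK--"), arow("b", "--VL")])


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        D = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float)
        tree = nj_tree(D, ["A", "B", "C"])
        dists = _patristic(tree)
        assert dists[("A", "B")] == pytest.approx(5)
        assert dists[("A", "C")] == pytest.approx(9)
        assert dists[("B", "C")] == pytest.approx(10)
        # closed form: x_A = (d_AB + d_AC - d_BC)/2 = 2
        edge = {lf.taxon.label: lf.edge.length
                for lf in tree.dtree.leaf_node_iter()}
        assert edge["A"] == pytest.approx(2.0)
        assert edge["B"] == pytest.approx(3.0)
        assert edge["C"] == pytest.approx(7.0)

    def test_additive_recovery(self):
        """NJ on additive matrices reproduces all pairwise path lengths."""
        rng = np.random.default_rng(17)
        for _ in range(30):
            n = int(rng.integers(4, 11))
            labels, D, _newick = random_additive_instance(n, rng)
            M = np.zeros((n, n))
            for i, a in enumerate(labels):
                for j, b in enumerate(labels):
                    if i != j:
                        M[i, j] = D[(a, b)]
            tree = nj_tree(M, labels)
            dists = _patristic(tree)
            for (a, b), d in dists.items():
                assert d == pytest.approx(D[(a, b)], abs=1e-9)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(23)
        labels, D, _ = random_additive_instance(7, rng)
        n = len(labels)
        M = np.array([[0 if i == j else D[(labels[i], labels[j])]
                       for j in range(n)] for i in range(n)])
        t1 = newick_string(nj_tree(M, labels))
        perm = list(rng.permutation(n))
        M2 = M[np.ix_(perm, perm)]
        t2 = newick_string(nj_tree(M2, [labels[i] for i in perm]))
        assert t1 == t2

    def test_asymmetric_rejected(self):
        M = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(TreeError):
            nj_tree(M, list("abc"))

    def test_matches_skbio_topology(self):
        """Independent cross-check against scikit-bio's NJ on a random
        additive matrix (same unrooted topology)."""
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj
        rng = np.random.default_rng(31)
        labels, D, _ = random_additive_instance(8, rng)
        n = len(labels)
        M = np.array([[0 if i == j else D[(labels[i], labels[j])]
                       for j in range(n)] for i in range(n)])
        ours = nj_tree(M, labels)
        theirs = skbio_nj(DistanceMatrix(M, labels))
        tns = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(data=newick_string(ours), schema="newick",
                               taxon_namespace=tns)
        t2 = dendropy.Tree.get(data=str(theirs).strip(), schema="newick",
                               taxon_namespace=tns)
        t1.encode_bipartitions()
        t2.encode_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(t1, t2) == 0


class TestMidpointRoot:
    def test_two_leaves(self):
        tree = parse_newick("(a:0.5,b:1.5);")
        rooted = midpoint_root(tree)
        depths = {lf.taxon.label: lf.distance_from_root()
                  for lf in rooted.dtree.leaf_node_iter()}
        assert depths == {"a": pytest.approx(1.0), "b": pytest.approx(1.0)}

    def test_ultrametric_crown_recovered(self):
        tree = parse_newick("((a:1,b:1):2,(c:1.5,d:1.5):1.5);")
        rooted = midpoint_root(tree)
        depths = [lf.distance_from_root() for lf in rooted.dtree.leaf_node_iter()]
        assert all(d == pytest.approx(3.0) for d in depths)

    def test_idempotent(self):
        tree = parse_newick("((a:1,b:2):0.5,(c:3,d:4):1);")
        once = midpoint_root(tree)
        twice = midpoint_root(once)
        assert newick_string(once) == newick_string(twice)

    def test_all_zero_lengths_deterministic(self):
        tree = parse_newick("((a:0,b:0):0,c:0);")
        rooted = midpoint_root(tree)
        assert rooted.rooted
        again = midpoint_root(parse_newick("((a:0,b:0):0,c:0);"))
        assert newick_string(rooted) == newick_string(again)


class TestNewick:
    def test_basic_parse(self):
        tree = parse_newick("(a:1,b:2,(c:3,d:4):5);")
        assert tree.leaf_labels() == ["a", "b", "c", "d"]
        assert not tree.rooted

    def test_file_round_trip(self, tmp_path):
        p = tmp_path / "t.nwk"
        tree = parse_newick("(a:1,b:2,(c:3,d:4):5);")
        write_newick(tree, p)
        back = read_newick(p)
        assert _patristic(back) == _patristic(tree)

    def test_random_trees_round_trip_topology(self, tmp_path):
        rng = np.random.default_rng(41)
        for rep in range(20):
            n = int(rng.integers(4, 12))
            _labels, D, newick = random_additive_instance(n, rng)
            t = parse_newick(newick)
            p = tmp_path / f"r{rep}.nwk"
            write_newick(t, p)
            back = read_newick(p)
            d1, d2 = _patristic(t), _patristic(back)
            assert d1.keys() == d2.keys()
            for k in d1:
                assert d1[k] == pytest.approx(d2[k], abs=1e-9)

    def test_unbalanced_parens_rejected(self):
        with pytest.raises(TreeError, match="parse"):
            parse_newick("((a,b);")
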