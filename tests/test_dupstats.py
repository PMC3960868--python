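"""Species-specific clades, duplication counts, and positional pair classes."""

import numpy as np
import pytest

from famscan.dupstats import (
    DupStatsError, species_specific_clades, clade_size_histogram,
    lineage_specific_duplications, classify_duplicate_pairs,
    positions_from_table, GenePosition, duplication_report, _resolved_binary,
)
from famscan.phylo import parse_newick
from oracles import (
    oracle_monospecific_nodes, oracle_maximal_monospecific_clades,
    random_species_tree,
)


def rooted(newick):
    t = parse_newick(newick)
    t.rooted = True
    t.dtree.is_rooted = True
    return t


def positions(*rows):
    return positions_from_table(list(rows))


class TestSpeciesClades:
    def test_simple_pair_and_singleton(self):
        tree = rooted("((a1:1,a2:1):1,b1:2);")
        clades = species_specific_clades(tree, {"a1": "A", "a2": "A", "b1": "B"})
        assert [(c.species, sorted(c.leaves)) for c in clades] == \
            [("A", ["a1", "a2"]), ("B", ["b1"])]

    def test_caterpillar_single_species(self):
        tree = rooted("((((a1:1,a2:1):1,a3:1):1,a4:1):1,a5:1);")
        clades = species_specific_clades(tree, {f"a{i}": "A" for i in range(1, 6)})
        assert len(clades) == 1 and clades[0].size == 5

    def test_alternating_species_all_singletons(self):
        tree = rooted("((((a1:1,b1:1):1,a2:1):1,b2:1):1,a3:1);")
        smap = {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B"}
        clades = species_specific_clades(tree, smap)
        assert all(c.size == 1 for c in clades)
        assert len(clades) == 5

    def test_partition_property(self):
        """Maximal monospecific clades of one species are disjoint and cover
        that species' leaves."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            newick, smap = random_species_tree(int(rng.integers(4, 30)), 3, rng)
            tree = rooted(newick)
            clades = species_specific_clades(tree, smap)
            for sp in set(smap.values()):
                sp_clades = [c for c in clades if c.species == sp]
                union = set()
                for c in sp_clades:
                    assert not union & c.leaves
                    union |= c.leaves
                assert union == {g for g, s in smap.items() if s == sp}

    def test_missing_species_rejected(self):
        tree = rooted("(a:1,b:1);")
        with pytest.raises(DupStatsError):
            species_specific_clades(tree, {"a": "A"})

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            newick, smap = random_species_tree(int(rng.integers(4, 40)), 4, rng)
            tree = rooted(newick)
            ours = {(c.species, c.leaves) for c in
                    species_specific_clades(tree, smap)}
            theirs = set(oracle_maximal_monospecific_clades(tree, smap))
            assert ours == theirs


class TestHistogram:
    def test_binning_example(self):
        from famscan.dupstats import SpeciesClade
        clades = [SpeciesClade("A", frozenset(f"g{i}" for i in range(n)))
                  for n in (12, 5, 5, 2)]
        binned, full = clade_size_histogram(clades)
        assert binned[">=10"] == 1 and binned["5"] == 2 and binned["other"] == 1
        assert full == {12: 1, 5: 2, 2: 1}

    def test_empty_list(self):
        binned, full = clade_size_histogram([])
        assert all(v == 0 for v in binned.values()) and full == {}

    def test_conservation(self):
        rng = np.random.default_rng(2)
        newick, smap = random_species_tree(25, 3, rng)
        clades = species_specific_clades(rooted(newick), smap)
        binned, _ = clade_size_histogram(clades)
        assert sum(binned.values()) == len(clades)


class TestLineageDuplications:
    def test_single_gene_zero(self):
        tree = rooted("(a1:1,b1:1);")
        assert lineage_specific_duplications(tree, {"a1": "A", "b1": "B"}, "A") == 0

    def test_three_gene_clade_two(self):
        tree = rooted("(((a1:1,a2:1):1,a3:1):1,b1:2);")
        smap = {"a1": "A", "a2": "A", "a3": "A", "b1": "B"}
        assert lineage_specific_duplications(tree, smap, "A") == 2

    def test_unknown_species_rejected(self):
        tree = rooted("(a1:1,b1:1);")
        with pytest.raises(DupStatsError):
            lineage_specific_duplications(tree, {"a1": "A", "b1": "B"}, "Z")

    def test_oracle_equivalence_and_size_identity(self):
        """Duplication counts equal an exhaustive node-scan oracle and the
        sum of (size - 1) over maximal clades, on random labeled trees."""
        rng = np.random.default_rng(33)
        for _ in range(50):
            newick, smap = random_species_tree(int(rng.integers(4, 50)), 3, rng)
            tree = rooted(newick)
            clades = species_specific_clades(tree, smap)
            for sp in sorted(set(smap.values())):
                got = lineage_specific_duplications(tree, smap, sp)
                assert got == oracle_monospecific_nodes(tree, smap, sp)
                assert got == sum(c.size - 1 for c in clades if c.species == sp)

    def test_polytomy_resolved_consistently(self):
        tree = rooted("((a1:1,a2:1,a3:1):1,b1:2);")
        smap = {"a1": "A", "a2": "A", "a3": "A", "b1": "B"}
        assert lineage_specific_duplications(tree, smap, "A") == 2


class TestPairClasses:
    SMAP = {"a1": "A", "a2": "A", "b1": "B"}

    def _clades(self, tree):
        return species_specific_clades(tree, self.SMAP)

    def test_adjacent_ranks_tandem(self):
        tree = rooted("((a1:1,a2:1):1,b1:2);")
        pos = positions(("a1", "chr1", 7000, 7500), ("a2", "chr1", 8000, 8500),
                        ("b1", "chr2", 100, 600))
        pairs = classify_duplicate_pairs(self._clades(tree), tree, pos)
        assert pairs == [(("a1", "a2"), "tandem")]

    def test_rank_gap_five_proximal(self):
        rows = [("a1", "chr1", 1000, 1500), ("a2", "chr1", 60_000, 60_500)]
        rows += [(f"x{i}", "chr1", 10_000 * (i + 1), 10_000 * (i + 1) + 500)
                 for i in range(4)]
        rows.append(("b1", "chr2", 100, 600))
        pos = positions(*rows)
        assert abs(pos["a1"].rank - pos["a2"].rank) == 5
        tree = rooted("((a1:1,a2:1):1,b1:2);")
        pairs = classify_duplicate_pairs(self._clades(tree), tree, pos)
        assert pairs == [(("a1", "a2"), "proximal")]

    def test_different_chromosomes_distal(self):
        tree = rooted("((a1:1,a2:1):1,b1:2);")
        pos = positions(("a1", "chr1", 1000, 1500), ("a2", "chr3", 1000, 1500),
                        ("b1", "chr2", 100, 600))
        pairs = classify_duplicate_pairs(self._clades(tree), tree, pos)
        assert pairs == [(("a1", "a2"), "distal")]

    def test_gap_above_threshold_distal(self):
        rows = [("a1", "chr1", 1000, 1500), ("a2", "chr1", 990_000, 990_500)]
        rows += [(f"x{i}", "chr1", 10_000 * (i + 2), 10_000 * (i + 2) + 500)
                 for i in range(15)]
        rows.append(("b1", "chr2", 100, 600))
        pos = positions(*rows)
        tree = rooted("((a1:1,a2:1):1,b1:2);")
        pairs = classify_duplicate_pairs(self._clades(tree), tree, pos)
        assert pairs == [(("a1", "a2"), "distal")]

    def test_missing_gene_rejected(self):
        tree = rooted("((a1:1,a2:1):1,b1:2);")
        pos = positions(("a1", "chr1", 1000, 1500), ("b1", "chr2", 100, 600))
        with pytest.raises(DupStatsError, match="a2"):
            classify_duplicate_pairs(self._clades(tree), tree, pos)

    def test_manifest_closed_loop(self, study):
        """Pair classes computed from the true tree and the planted positions
        reproduce the generator's per-cherry class truth exactly."""
        fam = study.family
        smap = fam.species_map()
        clades = species_specific_clades(fam.true_tree, smap)
        focal = [c for c in clades if c.species == study.focal_species]
        pos = positions_from_table(study.genome.position_rows())
        pairs = classify_duplicate_pairs(focal, _resolved_binary(fam.true_tree),
                                         pos)
        expected = {p: c for p, c in fam.expected_cherry_classes
                    if p[0].startswith(study.focal_species)}
        assert dict(pairs) == expected


class TestReport:
    def test_report_bundle(self, tmp_path):
        rng = np.random.default_rng(7)
        newick, smap = random_species_tree(12, 2, rng)
        tree = rooted(newick)
        report = duplication_report(tree, smap)
        assert sum(report.binned_histogram.values()) == len(report.clades)
        for sp, n in report.duplications_per_species.items():
            assert n == sum(c.size - 1 for c in report.clades
                            if c.species == sp)
        report.write_tsv(tmp_path / "r.tsv")
        text = report.summary_text()
        assert "Lineage-specific duplications" in text
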