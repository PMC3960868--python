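"""Naive gene calling, external predictors, and CDS/genome track merging."""

import stat

import numpy as np
import pytest

from famscan.core_seq import SeqRecord, translate, reverse_complement
from famscan.genome_scan import GenomicRegion, scan_genome, extract_region
from famscan.gene_models import (
    GeneModel, call_gene_naive, merge_gene_sets, run_external_predictor,
    assign_gene_ids, models_from_annotation, write_models_gff3,
)
from famscan.core_seq import read_gff3_features


def model(contig="c1", strand="+", start=100, end=400, source="cds_track",
          gene_id="g", partial=False):
    return GeneModel(gene_id=gene_id, contig_id=contig, strand=strand,
                     cds_intervals=[(start, end)], protein="M" * ((end - start) // 3),
                     source=source, partial=partial)


class TestNaiveCaller:
    def test_recovers_planted_truth_exactly(self, study, study_hmm):
        """Planted ATG..stop genes inside their window are recovered with the
        exact truth interval on both strands."""
        hits = scan_genome(study_hmm, study.genome.assembly, 20.0)
        truth = {(l.contig_id, l.strand): l for l in study.genome.planted()}
        recovered = set()
        strands_seen = set()
        for hit in hits:
            region = extract_region(hit, study.genome.assembly)
            m = call_gene_naive(region, hit, study.genome.assembly)
            if m is None:
                continue
            for l in study.genome.planted():
                if (m.contig_id, m.strand, m.cds_intervals[0]) == \
                        (l.contig_id, l.strand, (l.cds_start, l.cds_end)):
                    recovered.add(l.gene_id)
                    strands_seen.add(l.strand)
                    assert m.protein == l.protein
        assert recovered == {l.gene_id for l in study.genome.planted()}
        assert strands_seen == {"+", "-"}

    def test_partial_when_no_downstream_stop(self, study_hmm, study):
        """A hit close to the region 3' edge with no stop in range is partial."""
        protein = study.family.genes[0].protein
        from famscan.synth import _reverse_translate
        rng = np.random.default_rng(0)
        cds = "ATG" + _reverse_translate(protein[1:], rng)
        # region ends right after the CDS: no stop codon downstream
        seq = "TAA" + cds
        contig = SeqRecord("c", seq, "dna")
        hits = scan_genome(study_hmm, [contig], 20.0)
        assert hits
        region = GenomicRegion("c", 0, len(seq), "+")
        m = call_gene_naive(region, hits[0], [contig])
        assert m is not None and m.partial

    def test_no_orf_returns_none(self, study_hmm, study):
        """Stops on both sides within 60 codons leave no qualifying ORF."""
        domain = study.family.genes[0].domain
        from famscan.synth import _reverse_translate
        rng = np.random.default_rng(1)
        # TAA ATG <40 codons incl. domain> TGA -> ORF of ~41 codons < 60
        inner = "M" + domain[:39]
        cds = "ATG" + _reverse_translate(inner[1:], rng)
        seq = "GGG" * 30 + "TAA" + cds + "TGA" + "GGG" * 30
        contig = SeqRecord("c", seq, "dna")
        hits = scan_genome(study_hmm, [contig], 10.0, min_peptide=20)
        assert hits
        region = GenomicRegion("c", 0, len(seq), "+")
        m = call_gene_naive(region, hits[0], [contig])
        assert m is None


class TestMerge:
    def test_identical_models_keep_cds_track(self):
        cds = [model(source="cds_track", gene_id="a")]
        gen = [model(source="genome_track", gene_id="b")]
        merged = merge_gene_sets(cds, gen)
        assert len(merged) == 1 and merged[0].source == "cds_track"

    def test_disjoint_models_both_kept(self):
        cds = [model(start=100, end=400)]
        gen = [model(start=1000, end=1300, source="genome_track")]
        assert len(merge_gene_sets(cds, gen)) == 2

    def test_sixty_percent_overlap_merges(self):
        # spans 0-300 and 120-420: overlap 180 = 60% of each span
        cds = [model(start=0, end=300)]
        gen = [model(start=120, end=420, source="genome_track")]
        merged = merge_gene_sets(cds, gen, min_reciprocal_overlap=0.5)
        assert len(merged) == 1 and merged[0].source == "cds_track"

    def test_below_threshold_overlap_keeps_both(self):
        cds = [model(start=0, end=300)]
        gen = [model(start=210, end=510, source="genome_track")]  # 30% overlap
        assert len(merge_gene_sets(cds, gen)) == 2

    def test_opposite_strands_never_merge(self):
        cds = [model(strand="+")]
        gen = [model(strand="-", source="genome_track")]
        assert len(merge_gene_sets(cds, gen)) == 2

    def test_idempotent(self):
        cds = [model(start=0, end=300, gene_id="a")]
        gen = [model(start=120, end=420, source="genome_track", gene_id="b"),
               model(start=5000, end=5300, source="genome_track", gene_id="c")]
        merged = merge_gene_sets(cds, gen)
        again = merge_gene_sets(merged, gen)
        assert [(m.gene_id, m.span) for m in again] == \
            [(m.gene_id, m.span) for m in merged]

    def test_size_bound(self):
        cds = [model(start=i * 1000, end=i * 1000 + 300, gene_id=f"c{i}")
               for i in range(3)]
        gen = [model(start=i * 1000 + 5, end=i * 1000 + 305,
                     source="genome_track", gene_id=f"g{i}") for i in range(3)]
        merged = merge_gene_sets(cds, gen)
        assert len(merged) <= len(cds) + len(gen)
        assert len(merged) == len(cds)  # every pair crosses the threshold

    def test_assign_ids_deterministic(self):
        ms = [model(start=500, end=800, gene_id="x"),
              model(start=100, end=400, gene_id="y")]
        assign_gene_ids(ms, "AT")
        assert sorted(m.gene_id for m in ms) == ["AT001", "AT002"]
        by_pos = sorted(ms, key=lambda m: m.span[0])
        assert by_pos[0].gene_id == "AT001"


class TestExternalPredictor:
    REGION = GenomicRegion("c1", 1000, 2000, "+")

    @pytest.fixture()
    def assembly(self, study):
        rng = np.random.default_rng(2)
        from famscan.synth import _random_dna, _reverse_translate
        protein = study.family.genes[0].protein
        cds = "ATG" + _reverse_translate(protein[1:], rng)
        seq = _random_dna(rng, 1100, 0.4) + cds + _random_dna(rng, 2000, 0.4)
        return [SeqRecord("c1", seq, "dna")], len(cds), protein

    def _script(self, tmp_path, body):
        p = tmp_path / "mock_predictor.sh"
        p.write_text("#!/bin/sh\n" + body)
        p.chmod(p.stat().st_mode | stat.S_IEXEC)
        return str(p)

    def test_lifts_coordinates(self, tmp_path, assembly):
        contigs, cds_len, protein = assembly
        # region-local CDS at [100, 100+cds_len) -> genomic 1100..
        body = ("printf '##gff-version 3\\n"
                f"region\\tmock\\tCDS\\t101\\t{100 + cds_len}\\t.\\t+\\t0\\tID=m1\\n'\n")
        cmd = self._script(tmp_path, body)
        models = run_external_predictor(self.REGION, cmd + " {fasta}", contigs)
        assert len(models) == 1
        assert models[0].cds_intervals == [(1100, 1100 + cds_len)]
        assert models[0].protein == protein

    def test_failing_predictor_yields_empty(self, tmp_path, assembly):
        contigs, _, _ = assembly
        cmd = self._script(tmp_path, "exit 1\n")
        assert run_external_predictor(self.REGION, cmd + " {fasta}", contigs) == []

    def test_below_confirmation_dropped(self, tmp_path, assembly, study_hmm):
        contigs, _, _ = assembly
        # a model over random (non-domain) sequence: scores far below 20 bits
        body = ("printf '##gff-version 3\\n"
                "region\\tmock\\tCDS\\t7\\t306\\t.\\t+\\t0\\tID=m1\\n'\n")
        cmd = self._script(tmp_path, body)
        models = run_external_predictor(self.REGION, cmd + " {fasta}", contigs,
                                        hmm=study_hmm, confirmation_bits=20.0)
        assert models == []


class TestGff3Output:
    def test_models_round_trip_coordinates(self, tmp_path):
        ms = [model(start=100, end=400, gene_id="g1"),
              model(start=900, end=1200, gene_id="g2", strand="-")]
        p = tmp_path / "genes.gff3"
        write_models_gff3(ms, p)
        feats = read_gff3_features(p, types={"gene"})
        assert [(f["start"], f["end"], f["strand"]) for f in feats] == \
            [(100, 400, "+"), (900, 1200, "-")]
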