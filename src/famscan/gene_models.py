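"""Gene models: naive single-exon calling, external predictors, and track merging.

Candidate regions around genomic domain hits are turned into gene models by a
built-in naive caller (single exon: the hit's reading frame extended 5' to the
nearest in-frame ATG after the nearest upstream in-frame stop, and 3' to the
first in-frame stop).  Multi-exon genes can instead be recovered through a
pluggable external gene predictor invoked per region.  The CDS-track models
(from the genome project's own annotation) and genome-track models are merged:
a genome-track model is discarded when a same-strand CDS-track model overlaps
it reciprocally above a threshold, which operationalizes the "combine the two
prediction sets" step of the annotation workflow.

CDS intervals exclude the terminal stop codon, so ``translate(CDS) == protein``
holds exactly for complete models.
"""

from __future__ import annotations

import logging
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from famscan.core_seq import (
    SeqRecord, SequenceError, translate, reverse_complement,
    format_gff3_line, write_gff3_header, read_gff3_features, write_fasta,
)
from famscan.genome_scan import GenomicRegion, GenomicDomainHit, region_sequence
from famscan.profile_hmm import ProfileHMM, _viterbi_fast

logger = logging.getLogger(__name__)

MIN_ORF_CODONS = 60  # about one domain length


@dataclass
class GeneModel:
    """A candidate family-member gene anchored to genomic coordinates."""

    gene_id: str
    contig_id: str
    strand: str
    cds_intervals: list[tuple[int, int]]  # ordered 5'->3' on the coding strand
    protein: str
    source: str  # cds_track | genome_track | external
    partial: bool = False
    confirmation_score: float = float("nan")
    region: GenomicRegion | None = None
    origin_id: str = ""  # id before deterministic renumbering

    def __post_init__(self) -> None:
        if self.source not in ("cds_track", "genome_track", "external"):
            raise ValueError(f"unknown source {self.source!r}")
        ivs = sorted(self.cds_intervals)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if e1 > s2:
                raise ValueError(f"gene {self.gene_id}: overlapping CDS intervals")
        total = sum(e - s for s, e in ivs)
        if total % 3 and not self.partial:
            raise ValueError(f"gene {self.gene_id}: CDS length {total} not divisible by 3")

    @property
    def span(self) -> tuple[int, int]:
        return (min(s for s, _ in self.cds_intervals),
                max(e for _, e in self.cds_intervals))

    @property
    def span_length(self) -> int:
        s, e = self.span
        return e - s

    def cds_sequence(self, assembly: Sequence[SeqRecord]) -> str:
        """Spliced CDS read 5'->3' on the coding strand."""
        contig = next(c for c in assembly if c.id == self.contig_id)
        parts = [contig.residues[s:e] for s, e in sorted(self.cds_intervals)]
        seq = "".join(parts)
        return seq if self.strand == "+" else reverse_complement(seq)


def call_gene_naive(region: GenomicRegion, hit: GenomicDomainHit,
                    assembly: Sequence[SeqRecord],
                    min_orf_codons: int = MIN_ORF_CODONS) -> GeneModel | None:
    """Call a single-exon gene model around a genomic domain hit.

    Works on the coding strand of the region.  Returns ``None`` (with a logged
    reason) when no open reading frame of at least ``min_orf_codons`` codons
    contains the hit.
    """
    seq = region_sequence(region, assembly)
    if region.strand == "+":
        local_box = hit.box_start - region.start
    else:
        seq = reverse_complement(seq)
        local_box = region.end - hit.box_end
    if local_box < 0 or local_box >= len(seq):
        raise ValueError("hit box lies outside the region")
    frame = local_box % 3

    # 5' extension: nearest upstream in-frame stop, then nearest ATG after it.
    stop_pos = None
    for p in range(local_box - 3, frame - 3, -3):
        if translate(seq[p:p + 3]) == "*":
            stop_pos = p
            break
    partial = False
    if stop_pos is None:
        start = frame  # truncated at the region edge
        partial = True
    else:
        start = None
        for p in range(stop_pos + 3, local_box + 1, 3):
            if seq[p:p + 3] == "ATG":
                start = p
                break
        if start is None:
            logger.info("region %s:%d-%d: no start codon between upstream stop "
                        "and domain box", region.contig_id, region.start, region.end)
            return None

    # 3' extension to the first in-frame stop (excluded from the CDS).
    end = None
    for p in range(local_box, len(seq) - 2, 3):
        if translate(seq[p:p + 3]) == "*":
            end = p
            break
    if end is None:
        end = frame + 3 * ((len(seq) - frame) // 3)  # last full codon boundary
        partial = True

    n_codons = (end - start) // 3
    if n_codons < min_orf_codons:
        logger.info("region %s:%d-%d: ORF of %d codons below minimum %d",
                    region.contig_id, region.start, region.end, n_codons, min_orf_codons)
        return None
    protein = translate(seq[start:end])
    if "*" in protein:
        raise AssertionError("internal stop in called ORF")

    if region.strand == "+":
        g0, g1 = region.start + start, region.start + end
    else:
        g0, g1 = region.end - end, region.end - start
    return GeneModel(
        gene_id=f"naive:{region.contig_id}:{g0}-{g1}",
        contig_id=region.contig_id,
        strand=region.strand,
        cds_intervals=[(g0, g1)],
        protein=protein,
        source="genome_track",
        partial=partial,
        region=region,
    )


def run_external_predictor(region: GenomicRegion, command_template: str,
                           assembly: Sequence[SeqRecord],
                           hmm: ProfileHMM | None = None,
                           confirmation_bits: float = float("-inf"),
                           parser: str = "gff3") -> list[GeneModel]:
    """Run a user-configured gene predictor on a region and lift its models.

    ``command_template`` is formatted with ``{fasta}`` (path of the region
    FASTA written for the call); the predictor must print GFF3 with CDS
    features (region-local coordinates) to stdout.  Models whose protein fails
    the confirmation threshold against ``hmm`` are dropped.  Failures are
    logged per region and yield an empty list.
    """
    if parser != "gff3":
        raise ValueError(f"unsupported parser {parser!r}")
    seq = region_sequence(region, assembly)
    with tempfile.NamedTemporaryFile("w", suffix=".fasta", delete=False) as fh:
        fh.write(f">{region.contig_id}:{region.start}-{region.end}\n{seq}\n")
        fasta_path = fh.name
    cmd = command_template.format(fasta=fasta_path)
    try:
        proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
        if proc.returncode != 0:
            logger.warning("external predictor failed (exit %d) on %s:%d-%d",
                           proc.returncode, region.contig_id, region.start, region.end)
            return []
        with tempfile.NamedTemporaryFile("w", suffix=".gff3", delete=False) as out:
            out.write(proc.stdout)
            gff_path = out.name
        try:
            feats = read_gff3_features(gff_path, types={"CDS"})
        except (SequenceError, ValueError) as exc:
            logger.warning("external predictor output unparseable on %s:%d-%d: %s",
                           region.contig_id, region.start, region.end, exc)
            return []
        finally:
            Path(gff_path).unlink(missing_ok=True)
    finally:
        Path(fasta_path).unlink(missing_ok=True)

    by_gene: dict[str, list[dict]] = {}
    for f in feats:
        key = f["parent"] or f["id"] or "model1"
        by_gene.setdefault(key, []).append(f)
    models: list[GeneModel] = []
    for key, cds_feats in sorted(by_gene.items()):
        strand = cds_feats[0]["strand"]
        intervals = sorted((region.start + f["start"], region.start + f["end"])
                           for f in cds_feats)
        model = GeneModel(
            gene_id=f"ext:{region.contig_id}:{key}",
            contig_id=region.contig_id,
            strand=strand,
            cds_intervals=intervals,
            protein="",
            source="external",
        )
        try:
            model.protein = translate(model.cds_sequence(assembly)).rstrip("*")
        except (SequenceError, StopIteration) as exc:
            logger.warning("external model %s untranslatable: %s", key, exc)
            continue
        if hmm is not None:
            clean = model.protein.replace("*", "X")
            score = _viterbi_fast(hmm, hmm.encode(clean)) if clean else float("-inf")
            model.confirmation_score = score
            if score < confirmation_bits:
                logger.info("external model %s below confirmation threshold "
                            "(%.1f < %.1f bits), dropped", key, score, confirmation_bits)
                continue
        models.append(model)
    return models


def _reciprocal_overlap(a: GeneModel, b: GeneModel) -> float:
    """Min of overlap/span over the two models' CDS spans (0 if disjoint)."""
    (s1, e1), (s2, e2) = a.span, b.span
    ov = min(e1, e2) - max(s1, s2)
    if ov <= 0:
        return 0.0
    return min(ov / (e1 - s1), ov / (e2 - s2))


def merge_gene_sets(cds_track: Sequence[GeneModel], genome_track: Sequence[GeneModel],
                    min_reciprocal_overlap: float = 0.5) -> list[GeneModel]:
    """Combine CDS-track and genome-track models into one non-redundant set.

    CDS-track models are always kept.  A genome-track model is discarded when
    some same-strand CDS-track model overlaps it with reciprocal overlap at or
    above the threshold.  Output is sorted by (contig, span start).
    """
    merged = list(cds_track)
    for gm in genome_track:
        redundant = any(
            cm.contig_id == gm.contig_id and cm.strand == gm.strand
            and _reciprocal_overlap(cm, gm) >= min_reciprocal_overlap
            for cm in cds_track
        )
        if not redundant:
            merged.append(gm)
    merged.sort(key=lambda m: (m.contig_id, m.span[0], m.strand))
    logger.info("merge: %d cds-track + %d genome-track -> %d models",
                len(cds_track), len(genome_track), len(merged))
    return merged


def assign_gene_ids(models: Sequence[GeneModel], prefix: str) -> None:
    """Assign deterministic ids: ``<prefix><running number>`` in sorted order."""
    width = max(3, len(str(len(models))))
    for i, m in enumerate(sorted(models, key=lambda m: (m.contig_id, m.span[0], m.strand)),
                          start=1):
        if not m.origin_id:
            m.origin_id = m.gene_id
        m.gene_id = f"{prefix}{i:0{width}d}"


def models_from_annotation(gff_path, hit_ids: set[str],
                           assembly: Sequence[SeqRecord]) -> list[GeneModel]:
    """Build CDS-track gene models for annotated genes whose protein hit the profile.

    The annotation GFF3 must carry ``gene`` features (ID = gene id) and ``CDS``
    features with ``Parent`` pointing at the gene id.
    """
    feats = read_gff3_features(gff_path)
    cds_by_gene: dict[str, list[dict]] = {}
    strand_by_gene: dict[str, str] = {}
    for f in feats:
        if f["type"] == "CDS" and f["parent"] in hit_ids:
            cds_by_gene.setdefault(f["parent"], []).append(f)
            strand_by_gene[f["parent"]] = f["strand"]
    models = []
    for gid in sorted(cds_by_gene):
        cds = cds_by_gene[gid]
        model = GeneModel(
            gene_id=gid,
            contig_id=cds[0]["seqid"],
            strand=strand_by_gene[gid],
            cds_intervals=sorted((f["start"], f["end"]) for f in cds),
            protein="",
            source="cds_track",
        )
        model.protein = translate(model.cds_sequence(assembly)).rstrip("*")
        models.append(model)
    return models


# ---------------------------------------------------------------------------
# Output


def write_models_gff3(models: Sequence[GeneModel], path) -> None:
    """Write models as gene/mRNA/CDS features (1-based closed on output)."""
    with open(path, "w") as fh:
        write_gff3_header(fh)
        for m in models:
            s, e = m.span
            score = "." if m.confirmation_score != m.confirmation_score \
                else f"{m.confirmation_score:.2f}"
            attrs = f"ID={m.gene_id};source_track={m.source}"
            if m.origin_id:
                attrs += f";origin={m.origin_id}"
            fh.write(format_gff3_line(m.contig_id, "famscan", "gene", s, e, score,
                                      m.strand, ".", attrs))
            fh.write(format_gff3_line(m.contig_id, "famscan", "mRNA", s, e, ".",
                                      m.strand, ".", f"ID={m.gene_id}.t1;Parent={m.gene_id}"))
            for c0, c1 in sorted(m.cds_intervals):
                fh.write(format_gff3_line(m.contig_id, "famscan", "CDS", c0, c1, ".",
                                          m.strand, "0", f"Parent={m.gene_id}.t1"))


def write_proteins_fasta(models: Sequence[GeneModel], path) -> None:
    write_fasta(
        [SeqRecord(id=m.gene_id, residues=m.protein, alphabet="protein",
                   description=f"{m.contig_id}:{m.span[0]}-{m.span[1]}({m.strand})")
         for m in models if m.protein],
        path,
    )


def write_qc_report(models: Sequence[GeneModel], path) -> None:
    """Machine-readable QC table replacing a manual-inspection checkpoint."""
    with open(path, "w") as fh:
        fh.write("gene_id\tcontig\tstart\tend\tstrand\tsource\tpartial\t"
                 "confirmation_bits\tprotein_length\n")
        for m in models:
            s, e = m.span
            fh.write(f"{m.gene_id}\t{m.contig_id}\t{s}\t{e}\t{m.strand}\t{m.source}\t"
                     f"{int(m.partial)}\t{m.confirmation_score:.2f}\t{len(m.protein)}\n")
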