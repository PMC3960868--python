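"""Domain search in six-frame-translated genomes and windowed locus extraction.

Each contig is translated in all six frames; frame peptides are split at stop
codons into stop-free segments, and segments of at least ``min_peptide``
residues are scanned with the profile.  Hits are mapped back to genomic
coordinates through the frame coordinate map, and candidate loci are extracted
in a fixed window around the start of the detected domain (300 bp upstream and
19,700 bp downstream by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from famscan.core_seq import SeqRecord, six_frame_translate
from famscan.profile_hmm import ProfileHMM, DomainHit, _viterbi_fast, best_hit

logger = logging.getLogger(__name__)

DEFAULT_UPSTREAM_BP = 300
DEFAULT_DOWNSTREAM_BP = 19_700


@dataclass
class GenomicRegion:
    """A half-open genomic interval with strand and a boundary-clipping flag."""

    contig_id: str
    start: int
    end: int
    strand: str
    clipped: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid region [{self.start}, {self.end})")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class GenomicDomainHit:
    """A domain hit located on a genome contig.

    ``box_start``/``box_end`` bound the genomic interval of the aligned codons
    (the detected domain "box"); ``target_start``/``target_end`` are residue
    coordinates within the scanned stop-free segment.
    """

    target_id: str
    target_start: int
    target_end: int
    bit_score: float
    matched_states: tuple[int, int]
    path: str | None
    contig_id: str = ""
    strand: str = "+"
    frame_offset: int = 0
    box_start: int = 0
    box_end: int = 0
    segment_peptide: str = ""
    segment_offset: int = 0  # segment start within the frame peptide

    @property
    def box_biological_start(self) -> int:
        """Genomic coordinate of the first codon read 5'->3' on the hit strand."""
        return self.box_start if self.strand == "+" else self.box_end


def _segments(peptide: str, min_peptide: int):
    """Stop-free segments of a frame peptide as (offset, subpeptide)."""
    pos = 0
    for seg in peptide.split("*"):
        if len(seg) >= min_peptide:
            yield pos, seg
        pos += len(seg) + 1


def scan_genome(hmm: ProfileHMM, assembly: Sequence[SeqRecord], threshold_bits: float,
                min_peptide: int = 40) -> list[GenomicDomainHit]:
    """Scan an assembly for domain hits in all six reading frames.

    Overlapping hits from different frames on the same strand of a contig are
    collapsed to the best-scoring one (ties broken by lowest frame offset).
    Results are sorted by (contig, box_start).
    """
    raw: list[GenomicDomainHit] = []
    for contig in assembly:
        if contig.alphabet != "dna":
            raise ValueError(f"contig {contig.id!r} is not DNA")
        for frame in six_frame_translate(contig):
            for seg_off, seg in _segments(frame.peptide, min_peptide):
                idx = hmm.encode(seg)
                score = _viterbi_fast(hmm, idx)
                if score < threshold_bits:
                    continue
                hit = best_hit(hmm, SeqRecord(
                    id=f"{contig.id}|{frame.strand}{frame.frame_offset}|{seg_off}",
                    residues=seg, alphabet="protein"))
                p0 = seg_off + hit.target_start
                p1 = seg_off + hit.target_end
                box_start, box_end = frame.span_interval(p0, p1)
                raw.append(GenomicDomainHit(
                    target_id=hit.target_id,
                    target_start=hit.target_start,
                    target_end=hit.target_end,
                    bit_score=hit.bit_score,
                    matched_states=hit.matched_states,
                    path=hit.path,
                    contig_id=contig.id,
                    strand=frame.strand,
                    frame_offset=frame.frame_offset,
                    box_start=box_start,
                    box_end=box_end,
                    segment_peptide=seg,
                    segment_offset=seg_off,
                ))
    merged = _collapse_overlaps(raw)
    merged.sort(key=lambda h: (h.contig_id, h.box_start, h.strand))
    logger.info("genome scan: %d raw hits, %d after overlap collapse", len(raw), len(merged))
    return merged


def _collapse_overlaps(hits: list[GenomicDomainHit]) -> list[GenomicDomainHit]:
    """Collapse same-strand overlapping hits, keeping the best score
    (ties: lowest frame offset, then lowest box_start)."""
    by_key: dict[tuple[str, str], list[GenomicDomainHit]] = {}
    for h in hits:
        by_key.setdefault((h.contig_id, h.strand), []).append(h)
    kept: list[GenomicDomainHit] = []
    for group in by_key.values():
        group.sort(key=lambda h: (-h.bit_score, h.frame_offset, h.box_start))
        chosen: list[GenomicDomainHit] = []
        for h in group:
            if all(h.box_end <= c.box_start or h.box_start >= c.box_end for c in chosen):
                chosen.append(h)
        kept.extend(chosen)
    return kept


def extract_region(hit: GenomicDomainHit, assembly: Sequence[SeqRecord],
                   upstream_bp: int = DEFAULT_UPSTREAM_BP,
                   downstream_bp: int = DEFAULT_DOWNSTREAM_BP) -> GenomicRegion:
    """Extract the candidate locus window around a genomic domain hit.

    On the + strand the window is ``[box_start - upstream, box_start +
    downstream)``; on the - strand it mirrors about the biological box start
    (the higher-coordinate end): ``[box_end - downstream, box_end +
    upstream)``.  Windows are clipped at contig bounds, setting ``clipped``.
    """
    lengths = {c.id: len(c.residues) for c in assembly}
    if hit.contig_id not in lengths:
        raise ValueError(f"hit contig {hit.contig_id!r} not in assembly")
    L = lengths[hit.contig_id]
    if hit.strand == "+":
        start = hit.box_start - upstream_bp
        end = hit.box_start + downstream_bp
    else:
        start = hit.box_end - downstream_bp
        end = hit.box_end + upstream_bp
    clipped = start < 0 or end > L
    return GenomicRegion(
        contig_id=hit.contig_id,
        start=max(start, 0),
        end=min(end, L),
        strand=hit.strand,
        clipped=clipped,
    )


def region_sequence(region: GenomicRegion, assembly: Sequence[SeqRecord]) -> str:
    """Forward-strand genomic substring of a region."""
    for c in assembly:
        if c.id == region.contig_id:
            return c.residues[region.start:region.end]
    raise ValueError(f"contig {region.contig_id!r} not in assembly")


def write_hits_bed(hits: Sequence[GenomicDomainHit], path) -> None:
    """BED6 output: contig, box interval, hit name, score, strand."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(f"{h.contig_id}\t{h.box_start}\t{h.box_end}\t{h.target_id}\t"
                     f"{h.bit_score:.2f}\t{h.strand}\n")
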