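"""Sequence data model, FASTA/GFF3 I/O, translation, and six-frame translation.

Coordinates are 0-based half-open everywhere inside the toolkit; GFF3 emission
converts to 1-based closed at the boundary.  DNA is stored uppercase over
{A,C,G,T,N}; other IUPAC ambiguity codes are mapped to N with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

DNA_CHARS = frozenset("ACGTN")
# "-" is permitted in protein records so aligned FASTA rows are representable
PROTEIN_CHARS = frozenset("ACDEFGHIKLMNPQRSTVWYX*-")
_IUPAC_EXTRA = "RYSWKMBDHVU"
_DNA_CLEAN = str.maketrans(_IUPAC_EXTRA, "N" * len(_IUPAC_EXTRA))
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_STANDARD = CodonTable.unambiguous_dna_by_name["Standard"]
STANDARD_CODE: dict[str, str] = dict(_STANDARD.forward_table)
STANDARD_CODE.update({c: "*" for c in _STANDARD.stop_codons})


class SequenceError(ValueError):
    """Raised for malformed sequences or sequence files."""


@dataclass
class SeqRecord:
    """A named sequence over a declared alphabet.

    Parameters
    ----------
    id : str
        Unique identifier (non-empty).
    residues : str
        The sequence itself; stored uppercase.
    alphabet : {"dna", "protein"}
    description : str
        Free-text remainder of the FASTA header.
    """

    id: str
    residues: str
    alphabet: str = "dna"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("record id must be non-empty")
        if not self.residues:
            raise SequenceError(f"record {self.id!r}: residues must be non-empty")
        self.residues = self.residues.upper()
        if self.alphabet == "dna":
            bad = set(self.residues) - DNA_CHARS
            if bad & set(_IUPAC_EXTRA):
                logger.warning(
                    "record %s: IUPAC ambiguity codes %s mapped to N",
                    self.id, "".join(sorted(bad & set(_IUPAC_EXTRA))),
                )
                self.residues = self.residues.translate(_DNA_CLEAN)
                bad = set(self.residues) - DNA_CHARS
            if bad:
                raise SequenceError(
                    f"record {self.id!r}: invalid DNA characters {sorted(bad)}"
                )
        elif self.alphabet == "protein":
            bad = set(self.residues) - PROTEIN_CHARS
            if bad:
                raise SequenceError(
                    f"record {self.id!r}: invalid protein characters {sorted(bad)}"
                )
        else:
            raise SequenceError(f"unknown alphabet {self.alphabet!r}")

    def __len__(self) -> int:
        return len(self.residues)


def _infer_alphabet(residues: str) -> str:
    # strict ACGTN only: IUPAC ambiguity letters are all amino-acid codes too,
    # so anything beyond ACGTN is taken as protein unless the caller says dna
    return "dna" if set(residues.upper()) <= DNA_CHARS else "protein"


def read_fasta(path: str | Path, alphabet: str | None = None) -> list[SeqRecord]:
    """Read a FASTA file into a list of :class:`SeqRecord`.

    ``alphabet`` forces the alphabet of every record; by default it is inferred
    per record (all characters in the DNA/IUPAC set -> dna, else protein).
    Raises :class:`SequenceError` on an empty file or duplicate ids.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq)
        if rec.id in seen:
            raise SequenceError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        ab = alphabet or _infer_alphabet(residues)
        records.append(
            SeqRecord(id=rec.id, residues=residues, alphabet=ab,
                      description=rec.description[len(rec.id):].strip())
        )
    if not records:
        raise SequenceError(f"no records in {path}")
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complements)."""
    bad = set(seq.upper()) - DNA_CHARS
    if bad:
        raise SequenceError(f"invalid DNA characters {sorted(bad)}")
    return seq.upper().translate(_COMPLEMENT)[::-1]


def translate(cds: str, code: dict[str, str] | None = None) -> str:
    """Translate a CDS with the standard genetic code (or a custom table).

    One residue per complete codon; a trailing partial codon is ignored; stop
    codons render as ``*``; any codon containing N translates to ``X``.
    """
    cds = cds.upper()
    if len(cds) < 3:
        raise SequenceError("CDS shorter than one codon")
    table = STANDARD_CODE if code is None else code
    out = []
    for i in range(0, len(cds) - 2, 3):
        codon = cds[i:i + 3]
        if "N" in codon:
            out.append("X")
        else:
            try:
                out.append(table[codon])
            except KeyError as exc:
                raise SequenceError(f"untranslatable codon {codon!r}") from exc
    return "".join(out)


def read_code_table(path: str | Path) -> dict[str, str]:
    """Read a plain-text genetic-code override: one ``CODON<TAB>AA`` pair per line."""
    table: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        codon, aa = line.split()
        table[codon.upper()] = aa
    if len(table) != 64:
        raise SequenceError(f"genetic-code table has {len(table)} codons, expected 64")
    return table


@dataclass
class FrameTranslation:
    """One reading frame of a contig with an exact peptide->genome coordinate map.

    For a forward frame with offset ``f``, peptide position ``p`` maps to the
    genomic interval ``[f + 3p, f + 3p + 3)``.  For a reverse frame ``f`` on a
    contig of length ``L`` the codon at peptide position ``p`` occupies
    ``[L - f - 3p - 3, L - f - 3p)`` (the peptide reads along the reverse
    complement).
    """

    contig_id: str
    strand: str  # "+" or "-"
    frame_offset: int  # 0, 1, 2
    peptide: str
    contig_length: int

    def coord_map(self, p: int) -> tuple[int, int]:
        """Genomic half-open interval of the codon at peptide position ``p``."""
        if not 0 <= p < len(self.peptide):
            raise IndexError(f"peptide position {p} out of range")
        f = self.frame_offset
        if self.strand == "+":
            return (f + 3 * p, f + 3 * p + 3)
        L = self.contig_length
        return (L - f - 3 * p - 3, L - f - 3 * p)

    def span_interval(self, p_start: int, p_end: int) -> tuple[int, int]:
        """Genomic interval covered by peptide span ``[p_start, p_end)``."""
        a = self.coord_map(p_start)
        b = self.coord_map(p_end - 1)
        return (min(a[0], b[0]), max(a[1], b[1]))


def six_frame_translate(contig: SeqRecord) -> list[FrameTranslation]:
    """Translate a DNA record in all six reading frames.

    Returns three forward frames (offsets 0,1,2) followed by three frames on
    the reverse complement.  Internal stops are kept as ``*``; downstream
    scanning splits on them.
    """
    if contig.alphabet != "dna":
        raise SequenceError("six_frame_translate requires a DNA record")
    seq = contig.residues
    L = len(seq)
    if L < 3:
        raise SequenceError("contig shorter than one codon")
    rc = reverse_complement(seq)
    frames = []
    for strand, s in (("+", seq), ("-", rc)):
        for f in range(3):
            if L - f < 3:
                peptide = ""
            else:
                peptide = translate(s[f:])
            frames.append(
                FrameTranslation(
                    contig_id=contig.id, strand=strand, frame_offset=f,
                    peptide=peptide, contig_length=L,
                )
            )
    return frames


# ---------------------------------------------------------------------------
# GFF3 helpers

def write_gff3_header(fh) -> None:
    fh.write("##gff-version 3\n")


def format_gff3_line(seqid: str, source: str, ftype: str, start0: int, end0: int,
                     score: str, strand: str, phase: str, attributes: str) -> str:
    """Format one GFF3 line, converting 0-based half-open to 1-based closed."""
    return "\t".join([
        seqid, source, ftype, str(start0 + 1), str(end0), score, strand, phase,
        attributes,
    ]) + "\n"


def read_gff3_features(path: str | Path, types: set[str] | None = None) -> list[dict]:
    """Read GFF3 features into dicts with 0-based half-open coordinates.

    Returns a list of ``{"seqid", "type", "start", "end", "strand", "id",
    "parent", "attributes"}`` sorted as in the file.
    """
    feats: list[dict] = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 9:
            raise SequenceError(f"malformed GFF3 line: {line!r}")
        seqid, _source, ftype, start, end, _score, strand, _phase, attrs = parts
        if types is not None and ftype not in types:
            continue
        attributes = {}
        for kv in attrs.strip().split(";"):
            if kv and "=" in kv:
                k, v = kv.split("=", 1)
                attributes[k.strip()] = v.strip()
        feats.append({
            "seqid": seqid,
            "type": ftype,
            "start": int(start) - 1,
            "end": int(end),
            "strand": strand,
            "id": attributes.get("ID"),
            "parent": attributes.get("Parent"),
            "attributes": attributes,
        })
    return feats
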