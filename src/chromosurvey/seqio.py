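"""Readers and writers for the external formats the pipeline touches.

All coordinates crossing this module's boundary are 1-based inclusive.
Sequence formats go through Biopython; SAM goes through pysam; the simple
tabular dialects (12/13-column BLAST tabular, RepeatMasker ``.out``) are
parsed here with strict validation and line-number error reporting.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """A file does not parse under the named dialect."""


# ---------------------------------------------------------------------------
# domain types


@dataclass
class ReadRecord:
    """A sequencing read (or any named nucleotide sequence)."""

    id: str
    sequence: str
    quality: list[int] | None = None
    library: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"record {self.id!r}: empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise FormatError(
                f"record {self.id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class HomologyMatch:
    """One row of a tabular homology search (BLAST outfmt-6 dialect)."""

    query_id: str
    subject_id: str
    pident: float
    align_len: int
    mismatch: int = 0
    gapopen: int = 0
    qstart: int = 1
    qend: int = 1
    sstart: int = 1
    send: int = 1
    evalue: float = 0.0
    bitscore: float = 0.0
    ppos: float | None = None
    search_direction: str = "query-vs-protein"

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise FormatError(f"match {self.query_id}/{self.subject_id}: evalue < 0")
        if not (0.0 <= self.pident <= 100.0):
            raise FormatError(
                f"match {self.query_id}/{self.subject_id}: pident {self.pident} outside [0, 100]"
            )

    @property
    def reverse_orientation(self) -> bool:
        return self.sstart > self.send or self.qstart > self.qend


@dataclass
class RepeatAnnotation:
    """An interval on a read/contig assigned to a repeat family.

    ``superfamily_code`` uses the three-letter transposable-element codes
    (RLG = Gypsy LTR retroelement, RLC = Copia, DTC = CACTA DNA
    transposon, ...).
    """

    target_id: str
    start: int
    end: int
    family: str
    superfamily_code: str
    divergence: float = 0.0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(
                f"repeat on {self.target_id}: start {self.start} > end {self.end}"
            )
        if self.start < 1:
            raise FormatError(f"repeat on {self.target_id}: start {self.start} < 1")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class SamAlignment:
    """A minimal single-segment alignment: read, target, 1-based start and
    CIGAR-expanded aligned pairs (read_pos, target_pos), both 1-based."""

    read_id: str
    target_id: str
    start: int
    aligned_pairs: list[tuple[int, int]] = field(default_factory=list)
    read_sequence: str | None = None


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def _records_from_seqio(path: str | Path, fmt: str, library: str) -> list[ReadRecord]:
    records: list[ReadRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), fmt):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate id {rec.id!r}")
        seen.add(rec.id)
        qual = rec.letter_annotations.get("phred_quality")
        records.append(
            ReadRecord(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                quality=list(qual) if qual is not None else None,
                library=library,
            )
        )
    return records


def read_fasta(path: str | Path, library: str = "") -> list[ReadRecord]:
    """Read a FASTA file into ReadRecords. Duplicate ids raise FormatError."""
    return _records_from_seqio(path, "fasta", library)


def read_fastq(path: str | Path, library: str = "") -> list[ReadRecord]:
    return _records_from_seqio(path, "fastq", library)


def _to_seqrecords(records: Iterable[ReadRecord], with_qual: bool) -> list[SeqRecord]:
    out = []
    for r in records:
        sr = SeqRecord(Seq(r.sequence), id=r.id, description="")
        if with_qual:
            sr.letter_annotations["phred_quality"] = (
                list(r.quality) if r.quality is not None else [40] * len(r.sequence)
            )
        out.append(sr)
    return out


def write_fasta(records: Iterable[ReadRecord], path: str | Path) -> None:
    SeqIO.write(_to_seqrecords(records, with_qual=False), str(path), "fasta")


def write_fastq(records: Iterable[ReadRecord], path: str | Path) -> None:
    SeqIO.write(_to_seqrecords(records, with_qual=True), str(path), "fastq")


# ---------------------------------------------------------------------------
# BLAST tabular (12 columns; optional 13th = ppos)

_BLAST_COLS = 12


def read_blast_tab(
    path: str | Path,
    has_ppos: bool = False,
    search_direction: str = "query-vs-protein",
) -> list[HomologyMatch]:
    """Parse 12-column tabular homology matches.

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore [ppos]. Malformed lines are reported with
    their line number.
    """
    want = _BLAST_COLS + (1 if has_ppos else 0)
    matches: list[HomologyMatch] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != want:
                raise FormatError(
                    f"{path}:{lineno}: expected {want} columns, got {len(parts)}"
                )
            try:
                m = HomologyMatch(
                    query_id=parts[0],
                    subject_id=parts[1],
                    pident=float(parts[2]),
                    align_len=int(parts[3]),
                    mismatch=int(parts[4]),
                    gapopen=int(parts[5]),
                    qstart=int(parts[6]),
                    qend=int(parts[7]),
                    sstart=int(parts[8]),
                    send=int(parts[9]),
                    evalue=float(parts[10]),
                    bitscore=float(parts[11]),
                    ppos=float(parts[12]) if has_ppos else None,
                    search_direction=search_direction,
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            matches.append(m)
    return matches


def write_blast_tab(matches: Iterable[HomologyMatch], path: str | Path, with_ppos: bool = False) -> None:
    with open(path, "w") as fh:
        for m in matches:
            cols = [
                m.query_id,
                m.subject_id,
                f"{m.pident:.2f}",
                str(m.align_len),
                str(m.mismatch),
                str(m.gapopen),
                str(m.qstart),
                str(m.qend),
                str(m.sstart),
                str(m.send),
                f"{m.evalue:.2g}",
                f"{m.bitscore:.1f}",
            ]
            if with_ppos:
                cols.append(f"{m.ppos if m.ppos is not None else m.pident:.2f}")
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# RepeatMasker .out

#: RepeatMasker class/family strings mapped onto the three-letter codes.
_RM_CLASS_TO_CODE = {
    "LTR/Gypsy": "RLG",
    "LTR/Copia": "RLC",
    "LTR": "RLX",
    "DNA/CACTA": "DTC",
    "DNA/En-Spm": "DTC",
    "DNA/CMC-EnSpm": "DTC",
    "DNA/hAT": "DTA",
    "DNA/Harbinger": "DTH",
    "DNA/Mariner": "DTT",
    "DNA/MULE": "DTM",
    "LINE": "RIX",
    "LINE/L1": "RIL",
    "SINE": "RSX",
}

_CODE_RE = re.compile(r"^([A-Z]{3})[-_]")


def superfamily_from_family(family: str, rm_class: str = "") -> str:
    """Derive the three-letter superfamily code from a coded family name
    (e.g. ``DTC-Jorge`` -> ``DTC``) or from a RepeatMasker class string."""
    m = _CODE_RE.match(family)
    if m:
        return m.group(1)
    if rm_class in _RM_CLASS_TO_CODE:
        return _RM_CLASS_TO_CODE[rm_class]
    for prefix, code in _RM_CLASS_TO_CODE.items():
        if rm_class.startswith(prefix):
            return code
    return "XXX"


def read_repeatmasker_out(path: str | Path) -> list[RepeatAnnotation]:
    """Parse a RepeatMasker ``.out`` file (whitespace-delimited, 3 header
    lines). The complement-strand marker ``C`` is accepted; coordinates are
    already 1-based inclusive on the query."""
    annotations: list[RepeatAnnotation] = []
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines[3:], start=4):
        parts = line.split()
        if not parts:
            continue
        if len(parts) < 11:
            raise FormatError(f"{path}:{lineno}: too few columns ({len(parts)})")
        try:
            target = parts[4]
            start, end = int(parts[5]), int(parts[6])
            strand = parts[8]
            family = parts[9]
            rm_class = parts[10]
            divergence = float(parts[1])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        if strand not in ("+", "C"):
            raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
        annotations.append(
            RepeatAnnotation(
                target_id=target,
                start=start,
                end=end,
                family=family,
                superfamily_code=superfamily_from_family(family, rm_class),
                divergence=divergence,
            )
        )
    return annotations


def write_repeatmasker_out(annotations: Iterable[RepeatAnnotation], path: str | Path) -> None:
    """Emit annotations in the ``.out`` dialect read_repeatmasker_out accepts."""
    header = (
        "   SW   perc perc perc  query     position in query    matching repeat\n"
        "score   div. del. ins.  sequence  begin end   (left)   repeat    class/family\n"
        "\n"
    )
    code_to_class = {v: k for k, v in reversed(_RM_CLASS_TO_CODE.items())}
    with open(path, "w") as fh:
        fh.write(header)
        for a in annotations:
            rm_class = code_to_class.get(a.superfamily_code, "Unknown")
            fh.write(
                f"  250 {a.divergence:6.1f}  0.0  0.0  {a.target_id}  "
                f"{a.start} {a.end} (0) + {a.family}  {rm_class}  1 {len(a)} (0) 1\n"
            )


# ---------------------------------------------------------------------------
# minimal SAM


def read_sam_min(path: str | Path) -> list[SamAlignment]:
    """Read single-segment records from a SAM text file, expanding CIGARs
    into 1-based (read_pos, target_pos) aligned pairs. Unmapped records are
    dropped."""
    alignments: list[SamAlignment] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.reference_name is None:
                continue
            pairs = [
                (q + 1, r + 1)
                for q, r in rec.get_aligned_pairs(matches_only=True)
            ]
            alignments.append(
                SamAlignment(
                    read_id=rec.query_name,
                    target_id=rec.reference_name,
                    start=rec.reference_start + 1,
                    aligned_pairs=pairs,
                    read_sequence=rec.query_sequence,
                )
            )
    return alignments


def write_sam_min(
    alignments: Sequence[tuple[str, str, int, str, str]],
    references: dict[str, int],
    path: str | Path,
) -> None:
    """Write minimal SAM records.

    ``alignments`` rows are (read_id, target_id, 1-based start, cigar,
    read sequence); ``references`` maps target id to length.
    """
    ref_names = list(references)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": references[name]} for name in ref_names],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read_id, target_id, start, cigar, seq in alignments:
            a = pysam.AlignedSegment(out.header)
            a.query_name = read_id
            a.query_sequence = seq
            a.reference_id = ref_names.index(target_id)
            a.reference_start = start - 1
            a.cigarstring = cigar
            a.mapping_quality = 60
            out.write(a)


# ---------------------------------------------------------------------------
# GFF3 writer for gene models


def write_gff3_gene_models(models: Iterable, path: str | Path) -> None:
    """Write gene models (see genespace.GeneModel) as GFF3: one ``gene``
    feature per model on its reference CDS, one ``match_part`` per mapped
    segment, and ``gap`` features over the 'n'-filled runs."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for model in models:
            ref = model.reference_protein_id
            length = len(model.model_sequence)
            attrs = f"ID={ref};species={model.species};covered_len={model.covered_len}"
            if getattr(model, "conflict", False):
                attrs += ";overlap_conflict=true"
            fh.write(
                f"{ref}\tchromosurvey\tgene\t1\t{length}\t.\t+\t.\t{attrs}\n"
            )
            for seg_start, seg_end, source_id in model.segments:
                fh.write(
                    f"{ref}\tchromosurvey\tmatch_part\t{seg_start}\t{seg_end}\t.\t+\t.\t"
                    f"ID={ref}:{seg_start}-{seg_end};source_sequence={source_id}\n"
                )
            for gap_start, gap_end in _gap_runs(model.model_sequence):
                fh.write(
                    f"{ref}\tchromosurvey\tgap\t{gap_start}\t{gap_end}\t.\t+\t.\t"
                    f"ID={ref}:gap:{gap_start}\n"
                )


def _gap_runs(sequence: str) -> list[tuple[int, int]]:
    runs = []
    start = None
    for i, base in enumerate(sequence, start=1):
        if base in "nN":
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(sequence)))
    return runs
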