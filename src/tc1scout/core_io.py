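"""Sequence/annotation I/O and coordinate conventions.

All public coordinates in this package are 1-based inclusive (GenBank style).
BED output converts to 0-based half-open at the writing boundary and nowhere
else. Minus-strand extraction returns the reverse complement of the
plus-strand slice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .errors import AlphabetError, FormatError, ValidationError

NUCLEOTIDES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class GenomeSequence:
    """A named nucleotide sequence over {A,C,G,T,N}, uppercase."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sequence id must be non-empty")
        if not set(self.seq) <= NUCLEOTIDES:
            bad = sorted(set(self.seq) - NUCLEOTIDES)
            raise AlphabetError(f"invalid nucleotide characters {bad!r} in {self.id!r}")

    @property
    def length(self) -> int:
        return len(self.seq)

    def slice(self, iv: "Interval") -> str:
        """Extract the interval; minus strand returns the reverse complement."""
        if iv.start < 1 or iv.end > self.length:
            raise ValidationError(
                f"interval {iv.start}-{iv.end} outside {self.id!r} (length {self.length})"
            )
        sub = self.seq[iv.start - 1 : iv.end]
        return revcomp(sub) if iv.strand == "-" else sub


@dataclass(frozen=True)
class Interval:
    """1-based inclusive genomic interval."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValidationError(f"bad interval {self.start}-{self.end}")
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"bad strand {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, other: "Interval") -> bool:
        return self.seq_id == other.seq_id and self.start <= other.start and other.end <= self.end

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start <= other.end
            and other.start <= self.end
        )


def interval_length(iv: Interval) -> int:
    """Inclusive length: end - start + 1."""
    return iv.length()


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; case-insensitive input, uppercase output."""
    s = seq.upper()
    if not set(s) <= NUCLEOTIDES:
        bad = sorted(set(s) - NUCLEOTIDES)
        raise AlphabetError(f"invalid nucleotide characters {bad!r}")
    return s.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a (multi-)FASTA into GenomeSequence records, order preserved.

    Lowercase is normalized to uppercase. Empty files, files that do not
    start with a header, and records with empty ids raise FormatError.
    """
    path = Path(path)
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip():
                first = line
                break
        if not first.startswith(">"):
            raise FormatError(f"{path}: not a FASTA file (no '>' header)")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: record with empty id")
        seq = str(rec.seq).upper()
        try:
            records.append(GenomeSequence(id=rec.id, seq=seq))
        except AlphabetError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: empty FASTA")
    return records


def write_fasta(records: Iterable[GenomeSequence | tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, tuple):
                rid, seq = rec
            else:
                rid, seq = rec.id, rec.seq
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_protein_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read an amino-acid FASTA as (id, sequence) pairs, uppercased."""
    path = Path(path)
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append((rec.id, str(rec.seq).upper()))
    if not out:
        raise FormatError(f"{path}: empty FASTA")
    return out


@dataclass
class ElementAnnotation:
    """An element interval plus its five-part segmentation for GFF output.

    segments are (SO term, Interval) pairs; zero-length segments are
    represented by omitting the pair but still count in the length check via
    `segment_lengths`.
    """

    element: Interval
    segments: list[tuple[str, Interval]]
    segment_lengths: list[int] = field(default_factory=list)
    attributes: dict[str, str] = field(default_factory=dict)


def write_gff(
    elements: Sequence[ElementAnnotation],
    path: str | Path,
    seq_lengths: dict[str, int] | None = None,
    source: str = "tc1scout",
) -> None:
    """Write GFF3: one transposable_element parent per element + child segments.

    Coordinates are 1-based inclusive. Raises ValidationError when an element
    lies outside its sequence (requires seq_lengths) or when the recorded
    segment lengths do not sum to the parent length.
    """
    lines = ["##gff-version 3"]
    for n, ann in enumerate(elements, start=1):
        iv = ann.element
        if seq_lengths is not None:
            limit = seq_lengths.get(iv.seq_id)
            if limit is not None and iv.end > limit:
                raise ValidationError(f"element {iv.start}-{iv.end} outside {iv.seq_id}")
        if ann.segment_lengths:
            total = sum(ann.segment_lengths)
            if total != iv.length():
                raise ValidationError(
                    f"segment lengths sum to {total}, parent length {iv.length()}"
                )
        eid = ann.attributes.get("ID", f"te{n:04d}")
        attrs = ";".join(
            [f"ID={eid}"] + [f"{k}={v}" for k, v in ann.attributes.items() if k != "ID"]
        )
        lines.append(
            "\t".join(
                [iv.seq_id, source, "transposable_element", str(iv.start), str(iv.end),
                 ".", iv.strand, ".", attrs]
            )
        )
        for i, (term, seg) in enumerate(ann.segments, start=1):
            lines.append(
                "\t".join(
                    [seg.seq_id, source, term, str(seg.start), str(seg.end), ".",
                     seg.strand, ".", f"ID={eid}.{i};Parent={eid}"]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def interval_to_bed(iv: Interval, name: str = ".", score: int = 0) -> str:
    """BED6 line: 0-based half-open."""
    return "\t".join([iv.seq_id, str(iv.start - 1), str(iv.end), name, str(score), iv.strand])


def bed_to_interval(line: str) -> Interval:
    parts = line.rstrip("\n").split("\t")
    if len(parts) < 3:
        raise FormatError(f"bad BED line: {line!r}")
    strand = parts[5] if len(parts) >= 6 else "+"
    return Interval(parts[0], int(parts[1]) + 1, int(parts[2]), strand)
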