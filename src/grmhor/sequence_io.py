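"""Sequence and interval I/O.

Sequences are plain uppercase DNA strings over the alphabet {A, C, G, T, N}.
Ambiguous IUPAC codes are collapsed to N on input; soft-masking (lowercase)
is discarded by uppercasing.  Coordinates are 0-based half-open internally;
report writers convert to 1-based inclusive positions.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "NamedSequence",
    "Interval",
    "read_fasta",
    "write_fasta",
    "extract_region",
    "write_bed",
    "FastaFormatError",
]

_VALID = set("ACGTN")
# any letter that is not a concrete base or N becomes N (IUPAC ambiguity codes,
# plus anything unexpected)
_NORMALIZE = str.maketrans(
    {c: ("N" if c not in "ACGT" else c) for c in "ABCDEFGHIJKLMNOPQRSTUVWXYZ"}
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastaFormatError(ValueError):
    """Raised for malformed or empty FASTA input."""


@dataclass(frozen=True)
class NamedSequence:
    """A named DNA sequence normalized to uppercase {A,C,G,T,N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        bad = set(self.seq) - _VALID
        if bad:
            raise ValueError(f"sequence {self.id!r} contains invalid symbols {sorted(bad)!r}")

    @property
    def length(self) -> int:
        return len(self.seq)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval with strand."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"
    name: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def normalize_sequence(raw: str) -> str:
    """Uppercase and map every non-ACGT base letter to N."""
    return raw.upper().translate(_NORMALIZE)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | os.PathLike) -> list[NamedSequence]:
    """Read all records of a FASTA file, normalized to uppercase ACGTN.

    Raises FileNotFoundError for a missing path and FastaFormatError for an
    empty file or text that does not start with a FASTA header.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such FASTA file: {path}")
    with open(path) as fh:
        head = fh.read(1)
        if head == "":
            raise FastaFormatError(f"empty FASTA file: {path}")
        if head != ">":
            raise FastaFormatError(f"not FASTA (sequence before header?): {path}")
    records = [
        NamedSequence(id=rec.id, seq=normalize_sequence(str(rec.seq)))
        for rec in SeqIO.parse(path, "fasta")
    ]
    if not records:
        raise FastaFormatError(f"no FASTA records in {path}")
    return records


def write_fasta(path: str | os.PathLike, seqs: list[NamedSequence] | dict[str, str]) -> None:
    """Write sequences as FASTA, wrapped at 60 columns."""
    if isinstance(seqs, dict):
        seqs = [NamedSequence(id=k, seq=normalize_sequence(v)) for k, v in seqs.items()]
    records = [
        SeqRecord(Seq(s.seq), id=s.id, description="") for s in seqs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


def extract_region(seq: NamedSequence, iv: Interval) -> NamedSequence:
    """Extract iv from seq; minus-strand intervals return the reverse complement."""
    if iv.end > seq.length:
        raise IndexError(
            f"interval [{iv.start}, {iv.end}) out of bounds for {seq.id!r} (length {seq.length})"
        )
    sub = seq.seq[iv.start : iv.end]
    if iv.strand == "-":
        sub = reverse_complement(sub)
    return NamedSequence(id=f"{seq.id}:{iv.start + 1}-{iv.end}({iv.strand})", seq=sub)


def write_bed(path: str | os.PathLike, intervals: list[Interval], scores=None) -> None:
    """Write intervals as BED6 (chrom, start, end, name, score, strand)."""
    if scores is None:
        scores = [0] * len(intervals)
    with open(path, "w") as fh:
        for iv, score in zip(intervals, scores):
            fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{iv.name}\t{score}\t{iv.strand}\n")


def read_bed(path: str | os.PathLike) -> list[Interval]:
    """Read BED (3+ columns) into Interval records."""
    out: list[Interval] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            name = parts[3] if len(parts) > 3 else "."
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "+"
            out.append(
                Interval(seq_id=parts[0], start=int(parts[1]), end=int(parts[2]),
                         strand=strand, name=name)
            )
    return out
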