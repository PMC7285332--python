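"""Sequence and interval I/O shared by every other module.

Sequences are plain uppercase DNA strings over ``{A, C, G, T, N}``.
IUPAC ambiguity codes other than N are collapsed to N on input (real
read files contain them, and nothing downstream distinguishes more than
the four bases plus unknown). All coordinates in the package are
0-based, half-open, BED-style.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

_DNA = set("ACGTN")
_AMBIGUOUS = set("RYSWKMBDHVU")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class SequenceRecord:
    """A named DNA sequence, optionally with per-base quality scores."""

    id: str
    sequence: str
    qualities: Optional[list[int]] = None

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"record {self.id!r}: {len(self.qualities)} qualities for "
                f"{len(self.sequence)} bases"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class Interval:
    """A 0-based half-open interval on a named sequence."""

    seq_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )


def clean_sequence(raw: str, record_id: str = "?") -> str:
    """Uppercase *raw* and collapse ambiguity codes to N.

    Raises ``ValueError`` on characters that are not IUPAC nucleotide
    codes at all.
    """
    seq = raw.upper()
    if set(seq) <= _DNA:
        return seq
    out = []
    n_converted = 0
    for ch in seq:
        if ch in _DNA:
            out.append(ch)
        elif ch in _AMBIGUOUS:
            out.append("N")
            n_converted += 1
        else:
            raise ValueError(f"record {record_id!r}: non-nucleotide character {ch!r}")
    logger.warning(
        "record %r: converted %d ambiguity code(s) to N", record_id, n_converted
    )
    return "".join(out)


def _open_maybe_gzip(path: Path, mode: str = "rt"):
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, mode)
    return open(path, mode)


def _sniff_format(path: Path) -> str:
    with _open_maybe_gzip(path) as fh:
        first = fh.read(1)
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise ValueError(f"{path}: cannot auto-detect format (starts with {first!r})")


def load_sequences(path, format: str = "auto") -> list[SequenceRecord]:
    """Load FASTA or FASTQ (optionally gzipped) into SequenceRecords.

    ``format`` is one of ``fasta``, ``fastq`` or ``auto`` (sniffed from
    the first byte). Ambiguity codes are converted to N with a warning;
    an empty file is an error.
    """
    path = Path(path)
    if format == "auto":
        format = _sniff_format(path)
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}")
    records: list[SequenceRecord] = []
    with _open_maybe_gzip(path) as fh:
        for rec in SeqIO.parse(fh, format):
            seq = clean_sequence(str(rec.seq), rec.id)
            if len(seq) == 0:
                raise ValueError(f"{path}: record {rec.id!r} has an empty sequence")
            quals = rec.letter_annotations.get("phred_quality")
            records.append(
                SequenceRecord(
                    id=rec.id,
                    sequence=seq,
                    qualities=list(quals) if quals is not None else None,
                )
            )
    if not records:
        raise ValueError(f"{path}: no sequence records found")
    return records


def write_sequences(
    records: Sequence[SequenceRecord],
    path,
    format: str = "fasta",
    width: int = 80,
    descriptions: Optional[dict[str, str]] = None,
) -> None:
    """Write records as FASTA (wrapped at *width*) or FASTQ.

    ``descriptions`` optionally maps record ids to extra header text.
    Round trip with :func:`load_sequences` preserves ids and sequences
    exactly.
    """
    if not records:
        raise ValueError("refusing to write an empty record list")
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported output format {format!r}")
    path = Path(path)
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for rec in records:
            if format == "fasta":
                desc = descriptions.get(rec.id, "")
                header = f">{rec.id} {desc}".rstrip()
                fh.write(header + "\n")
                for i in range(0, len(rec.sequence), width):
                    fh.write(rec.sequence[i : i + width] + "\n")
            else:
                quals = rec.qualities or [40] * len(rec.sequence)
                qstr = "".join(chr(q + 33) for q in quals)
                fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{qstr}\n")


def reverse_complement(sequence: str) -> str:
    """Reverse complement of a DNA string; N maps to N."""
    if not set(sequence) <= _DNA:
        bad = sorted(set(sequence) - _DNA)
        raise ValueError(f"non-DNA character(s) {bad} in sequence")
    return sequence.translate(_COMPLEMENT)[::-1]


def rotate_circular(record: SequenceRecord, offset: int) -> SequenceRecord:
    """Move the last *offset* bases of a circular sequence to its front.

    ``rotate_circular(s, k)`` returns ``s[n-k:] + s[:n-k]``; rotating by
    0 (or by the full length) is the identity. Used to check that the
    coverage of a circular contig stays uniform across the origin.
    """
    n = len(record.sequence)
    if not (0 <= offset <= n):
        raise ValueError(f"rotation offset {offset} out of range for length {n}")
    off = offset % n
    seq = record.sequence[n - off :] + record.sequence[: n - off]
    quals = None
    if record.qualities is not None:
        quals = record.qualities[n - off :] + record.qualities[: n - off]
    return SequenceRecord(id=record.id, sequence=seq, qualities=quals)


# ---------------------------------------------------------------------------
# BED intervals

def write_bed(intervals: Iterable[Interval], path, names: Optional[Sequence[str]] = None) -> None:
    """Write intervals as 3- or 4-column BED."""
    names = list(names) if names is not None else None
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            cols = [iv.seq_id, str(iv.start), str(iv.end)]
            if names is not None:
                cols.append(names[i])
            fh.write("\t".join(cols) + "\n")


def load_intervals(path) -> list[Interval]:
    """Read intervals from BED (0-based) or GFF3 (1-based, converted)."""
    path = Path(path)
    out: list[Interval] = []
    with _open_maybe_gzip(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if _looks_like_gff(cols):
                out.append(Interval(cols[0], int(cols[3]) - 1, int(cols[4])))
            else:
                out.append(Interval(cols[0], int(cols[1]), int(cols[2])))
    return out


def _looks_like_gff(cols: list[str]) -> bool:
    # GFF3: 9 columns, col 4/5 numeric, col 7 a strand symbol
    return (
        len(cols) >= 8
        and cols[3].isdigit()
        and cols[4].isdigit()
        and cols[6] in ("+", "-", ".", "?")
    )
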