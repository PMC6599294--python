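"""Chunked FASTQ input/output with quality-encoding detection.

FASTQ files are streamed in fixed-size blocks of reads so that memory use is
bounded by the block size rather than the file size.  Qualities are normalised
to integer Phred scores on input; five legacy encodings are recognised
(Sanger, Solexa, Illumina 1.3+/1.5+/>=1.8) and output is always written at
Phred+33.  gzip compression is detected from the file's magic bytes, not its
extension.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from itertools import islice
from typing import IO, Iterator, Optional, Sequence

__all__ = [
    "Read",
    "EncodingInfo",
    "ChunkSpec",
    "MalformedFastqError",
    "detect_encoding",
    "detect_file_encoding",
    "normalize_quality",
    "read_chunks",
    "write_reads",
    "FastqWriter",
]

VALID_BASES = frozenset("ACGTN")

#: Admissible ASCII intervals for each quality dialect.
ENCODING_RANGES = {
    "sanger": (33, 73),
    "illumina18plus": (33, 74),
    "solexa": (59, 104),
    "illumina13": (64, 104),
    "illumina15": (66, 104),
}


class MalformedFastqError(ValueError):
    """Raised for records that violate the 4-line FASTQ grammar.

    ``line`` is the 1-based line number of the offending line.
    """

    def __init__(self, line: int, message: str):
        self.line = line
        super().__init__(f"line {line}: {message}")


@dataclass(slots=True)
class Read:
    """A single FASTQ record with encoding-normalised qualities.

    ``id`` excludes the leading ``@``; an optional ``comment`` holds anything
    after the first whitespace of the header.  ``quals`` are integer Phred
    scores of the same length as ``bases``.
    """

    id: str
    bases: str
    quals: tuple[int, ...]
    comment: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.id!r}: bases length {len(self.bases)} != "
                f"quals length {len(self.quals)}"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True, slots=True)
class EncodingInfo:
    """A detected quality dialect and its ASCII offset."""

    name: str
    offset: int
    observed_min: int
    observed_max: int

    def __post_init__(self) -> None:
        if self.name not in ENCODING_RANGES:
            raise ValueError(f"unknown encoding name {self.name!r}")
        expected = 33 if self.name in ("sanger", "illumina18plus") else 64
        if self.offset != expected:
            raise ValueError(f"{self.name} requires offset {expected}")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "offset": self.offset,
            "observed_min": self.observed_min,
            "observed_max": self.observed_max,
        }


@dataclass(frozen=True, slots=True)
class ChunkSpec:
    """Number of reads processed per streaming cycle."""

    chunk_size: int = 10000

    def __post_init__(self) -> None:
        if self.chunk_size < 1:
            raise ValueError("chunk_size must be >= 1")


def detect_encoding(quality_strings: Sequence[str]) -> EncodingInfo:
    """Classify raw ASCII quality lines into one of the five dialects.

    The decision uses only the observed ASCII range and is therefore
    invariant under permutation of the input lines:

    * min < 59          -> offset 33 (``illumina18plus`` if max > 73, else ``sanger``)
    * 59 <= min < 64    -> ``solexa``
    * 64 <= min < 66    -> ``illumina13``
    * min >= 66         -> ``illumina15``

    Raises ``ValueError`` when the observed range fits no dialect
    (min below 33 or a non-printable maximum) or no characters were seen.
    """
    lo, hi = None, None
    for line in quality_strings:
        for ch in line:
            o = ord(ch)
            if lo is None or o < lo:
                lo = o
            if hi is None or o > hi:
                hi = o
    if lo is None or hi is None:
        raise ValueError("no quality characters observed")
    if lo < 33:
        raise ValueError(
            f"observed ASCII minimum {lo} is below 33: no known quality dialect"
        )
    if hi > 126:
        raise ValueError(f"observed ASCII maximum {hi} is not printable")
    if lo < 59:
        name = "illumina18plus" if hi > 73 else "sanger"
        offset = 33
    elif lo < 64:
        name, offset = "solexa", 64
    elif lo < 66:
        name, offset = "illumina13", 64
    else:
        name, offset = "illumina15", 64
    return EncodingInfo(name=name, offset=offset, observed_min=lo, observed_max=hi)


def normalize_quality(raw: str, enc: EncodingInfo) -> tuple[int, ...]:
    """Convert a raw ASCII quality line to integer Phred scores.

    Solexa qualities are log-odds scores; they are mapped onto the Phred
    scale with Q = round(10 * log10(10^(Qs/10) + 1)).
    """
    if enc.name == "solexa":
        out = []
        for ch in raw:
            qs = ord(ch) - 64
            out.append(int(round(10.0 * math.log10(10.0 ** (qs / 10.0) + 1.0))))
        return tuple(out)
    offset = enc.offset
    out = []
    for ch in raw:
        q = ord(ch) - offset
        if q < 0:
            raise ValueError(
                f"quality character {ch!r} (ASCII {ord(ch)}) below "
                f"offset {offset} for encoding {enc.name}"
            )
        out.append(q)
    return tuple(out)


def _open_text(path) -> IO[str]:
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt", encoding="ascii")
    return open(path, "rt", encoding="ascii")


def _iter_raw_records(path) -> Iterator[tuple[str, Optional[str], str, str]]:
    """Yield (id, comment, bases, raw_quality) tuples, validating the grammar."""
    with _open_text(path) as fh:
        line_no = 0
        while True:
            header = fh.readline()
            if header == "":
                return
            line_no += 1
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise MalformedFastqError(line_no, "expected header starting with '@'")
            lines = [fh.readline() for _ in range(3)]
            if any(ln == "" for ln in lines):
                missing = line_no + 1 + [ln == "" for ln in lines].index(True)
                raise MalformedFastqError(
                    missing, "truncated record (file is not a multiple of 4 lines)"
                )
            seq, plus, qual = (ln.rstrip("\n") for ln in lines)
            if not plus.startswith("+"):
                raise MalformedFastqError(line_no + 2, "expected '+' separator line")
            seq = seq.upper()
            bad = set(seq) - VALID_BASES
            if bad:
                raise MalformedFastqError(
                    line_no + 1,
                    f"invalid base character(s) {sorted(bad)!r} in read",
                )
            if len(seq) != len(qual):
                raise MalformedFastqError(
                    line_no + 3,
                    f"quality length {len(qual)} != sequence length {len(seq)}",
                )
            name = header[1:]
            parts = name.split(None, 1)
            rid = parts[0] if parts else ""
            comment = parts[1] if len(parts) == 2 else None
            yield rid, comment, seq, qual
            line_no += 3


def detect_file_encoding(path, max_reads: int = 10000) -> Optional[EncodingInfo]:
    """Detect the quality dialect from the first ``max_reads`` records.

    Returns ``None`` for an empty file.
    """
    quals = [rec[3] for rec in islice(_iter_raw_records(path), max_reads)]
    if not quals:
        return None
    return detect_encoding(quals)


def read_chunks(
    path,
    spec: Optional[ChunkSpec] = None,
    enc: Optional[EncodingInfo] = None,
) -> Iterator[list[Read]]:
    """Stream a FASTQ file as lists of at most ``spec.chunk_size`` reads.

    When ``enc`` is not given it is auto-detected from the first chunk.
    Concatenating the chunks reproduces the file order exactly, for any
    chunk size.
    """
    spec = spec or ChunkSpec()
    raw_it = _iter_raw_records(path)
    chunk = list(islice(raw_it, spec.chunk_size))
    if not chunk:
        return
    if enc is None:
        enc = detect_encoding([rec[3] for rec in chunk])
    while chunk:
        yield [
            Read(id=rid, comment=comment, bases=seq, quals=normalize_quality(qual, enc))
            for rid, comment, seq, qual in chunk
        ]
        chunk = list(islice(raw_it, spec.chunk_size))


def _format_record(read: Read) -> str:
    header = f"@{read.id}" if read.comment is None else f"@{read.id} {read.comment}"
    qual = "".join(chr(min(q, 93) + 33) for q in read.quals)
    return f"{header}\n{read.bases}\n+\n{qual}\n"


class FastqWriter:
    """Incremental FASTQ writer, always emitting Phred+33 qualities."""

    def __init__(self, path, compress: bool = False):
        self._fh: IO[str] = (
            gzip.open(path, "wt", encoding="ascii")
            if compress
            else open(path, "wt", encoding="ascii")
        )
        self.count = 0

    def write(self, reads: Sequence[Read]) -> int:
        for read in reads:
            self._fh.write(_format_record(read))
        self.count += len(reads)
        return len(reads)

    def close(self) -> None:
        self._fh.close()

    def __enter__(self) -> "FastqWriter":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def write_reads(reads: Sequence[Read], path, compress: bool = False) -> int:
    """Write reads as 4-line FASTQ records; returns the number written."""
    with FastqWriter(path, compress=compress) as writer:
        writer.write(reads)
        return writer.count
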