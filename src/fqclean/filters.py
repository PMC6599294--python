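"""Whole-read removal filters.

Each filter is a pure predicate on a single read returning a
:class:`FilterDecision`; deduplication is the one stateful exception, keeping
a persistent seen-set across streaming chunks.  All threshold comparisons are
inclusive: a read exactly at the threshold is kept.
"""

from __future__ import annotations

import hashlib
import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

from .fastq_io import Read

__all__ = [
    "FilterDecision",
    "filter_n",
    "filter_complexity",
    "filter_length",
    "filter_mean_quality",
    "Deduplicator",
    "dedup_stream",
    "dinucleotide_entropy_ratio",
]

_HMAX = math.log2(16.0)  # maximal entropy of the 16-letter dinucleotide alphabet


@dataclass(frozen=True, slots=True)
class FilterDecision:
    keep: bool
    reason: Optional[str] = None

    def __post_init__(self) -> None:
        if self.keep and self.reason is not None:
            raise ValueError("kept reads carry no removal reason")
        if not self.keep and self.reason is None:
            raise ValueError("removed reads must name the filter")


def filter_n(read: Read, max_n: int = 0) -> FilterDecision:
    """Keep reads with at most ``max_n`` ambiguous (N) bases."""
    if read.bases.count("N") <= max_n:
        return FilterDecision(True)
    return FilterDecision(False, "n")


def dinucleotide_entropy_ratio(bases: str) -> Optional[float]:
    """Shannon entropy of overlapping dinucleotide frequencies, over log2(16).

    Windows containing N are excluded; returns ``None`` when no valid window
    exists (too short or entirely ambiguous).
    """
    counts: Counter[str] = Counter()
    for i in range(len(bases) - 1):
        window = bases[i : i + 2]
        if "N" not in window:
            counts[window] += 1
    total = sum(counts.values())
    if total == 0:
        return None
    h = -sum((c / total) * math.log2(c / total) for c in counts.values())
    return h / _HMAX


def filter_complexity(read: Read, threshold: float = 0.5) -> FilterDecision:
    """Remove low-complexity reads by normalised dinucleotide entropy.

    A homopolymer scores 0, a perfect two-letter repeat about 0.25, and a
    random sequence close to 1.  Reads too short to score (fewer than two
    bases, or no N-free dinucleotide) are kept unconditionally.
    """
    ratio = dinucleotide_entropy_ratio(read.bases)
    if ratio is None or ratio >= threshold:
        return FilterDecision(True)
    return FilterDecision(False, "complexity")


def filter_length(read: Read, min_length: int = 0) -> FilterDecision:
    """Keep reads of length at least ``min_length``."""
    if len(read.bases) >= min_length:
        return FilterDecision(True)
    return FilterDecision(False, "length")


def filter_mean_quality(read: Read, min_q: float = 20.0) -> FilterDecision:
    """Keep reads whose arithmetic mean Phred score is at least ``min_q``.

    Empty reads have no defined mean and are removed.
    """
    if len(read.quals) == 0:
        return FilterDecision(False, "meanq")
    if sum(read.quals) / len(read.quals) >= min_q:
        return FilterDecision(True)
    return FilterDecision(False, "meanq")


class Deduplicator:
    """Streaming duplicate-read filter.

    Equality is exact identity of the base string only — identifiers and
    qualities are ignored, and reverse complements are not collapsed.  A
    SHA-1 digest of the sequence is stored per distinct read so memory grows
    with the number of distinct sequences, not their length; the digest
    collision probability is negligible at any realistic library size.
    """

    def __init__(self) -> None:
        self._seen: set[bytes] = set()

    def check(self, read: Read) -> FilterDecision:
        digest = hashlib.sha1(read.bases.encode("ascii")).digest()
        if digest in self._seen:
            return FilterDecision(False, "duplicate")
        self._seen.add(digest)
        return FilterDecision(True)


def dedup_stream(reads: Iterable[Read]) -> Iterator[Read]:
    """Yield the first occurrence of each distinct sequence, in input order."""
    dedup = Deduplicator()
    for read in reads:
        if dedup.check(read).keep:
            yield read
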