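"""Read trimming: adapters (flank and internal), 5' quality, fixed lengths.

The adapter trimmer looks for two kinds of matches between an adapter and a
read, both with a mismatch budget of ``floor(error_rate * matched_length)``:

* *internal* — the full adapter aligned anywhere within the read;
* *flank* — a partial overlap of length ``k >= min_overlap`` anchored at a
  read end: adapter prefix against the read's 3' suffix when trimming
  rightwards, adapter suffix against the read's 5' prefix when trimming
  leftwards.

Right-trimming keeps the read up to the *smallest* match start; left-trimming
keeps the read from the *largest* match end, so multiple matches are trimmed
through the outermost one.  An N in the read never matches any adapter base.
When ``allow_indels`` is set, Levenshtein distance replaces Hamming distance
under the same budget.  Coordinates are 0-based, half-open.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

from .fastq_io import Read

__all__ = [
    "AdapterSpec",
    "TrimResult",
    "find_adapter_matches",
    "adapter_trim",
    "quality_trim_5p",
    "fixed_trim",
]


@dataclass(frozen=True, slots=True)
class AdapterSpec:
    """An adapter sequence and its matching parameters."""

    sequence: str
    error_rate: float = 0.1
    min_overlap: int = 5
    allow_indels: bool = False
    direction: str = "right"

    def __post_init__(self) -> None:
        if not self.sequence or set(self.sequence) - set("ACGT"):
            raise ValueError("adapter must be a non-empty string over {A,C,G,T}")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if not 1 <= self.min_overlap <= len(self.sequence):
            raise ValueError("min_overlap must be in [1, adapter length]")
        if self.direction not in ("right", "left"):
            raise ValueError("direction must be 'right' or 'left'")


@dataclass(frozen=True, slots=True)
class TrimResult:
    read: Read
    bases_removed: int
    matched: bool


def _hamming_within(a: str, b: str, budget: int) -> int:
    """Mismatch count of equal-length strings, or -1 once it exceeds budget."""
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > budget:
                return -1
    return mism


def _levenshtein_within(a: str, b: str, budget: int) -> int:
    """Levenshtein distance, or -1 if it exceeds ``budget``."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cost = 0 if ca == cb else 1
            cur.append(min(prev[j - 1] + cost, prev[j] + 1, cur[j - 1] + 1))
        prev = cur
    return prev[-1] if prev[-1] <= budget else -1


def _semiglobal_end_dists(pattern: str, text: str) -> list[int]:
    """d[j] = min over s of edit distance between ``pattern`` and ``text[s:j]``.

    Standard semiglobal DP with a free alignment start in the text.
    """
    m = len(pattern)
    col = list(range(m + 1))
    dists = [col[m]]
    for ch in text:
        new = [0] * (m + 1)
        for i in range(1, m + 1):
            cost = 0 if pattern[i - 1] == ch else 1
            new[i] = min(col[i - 1] + cost, col[i] + 1, new[i - 1] + 1)
        col = new
        dists.append(col[m])
    return dists


def _best_window(pattern: str, text: str, anchor: int, budget: int, from_start: bool):
    """Best-scoring window anchored at ``anchor``; returns (lo, hi) or None."""
    m = len(pattern)
    best = None
    w_lo, w_hi = max(1, m - budget), m + budget
    for w in range(w_lo, w_hi + 1):
        if from_start:
            lo, hi = anchor, anchor + w
            if hi > len(text):
                break
        else:
            lo, hi = anchor - w, anchor
            if lo < 0:
                break
        d = _levenshtein_within(pattern, text[lo:hi], budget)
        if d >= 0 and (best is None or d < best[0]):
            best = (d, (lo, hi))
    return best[1] if best else None


def _internal_matches_edit(bases: str, adapter: str, budget: int) -> list[tuple[int, int]]:
    """All edit-distance internal matches, anchored by admissible starts and ends.

    An end ``j`` (or start ``s``) is admissible when some window ending (or
    starting) there is within the budget; each anchor is reported with its
    best-scoring window so the outermost match boundaries — the only ones the
    keep-rule uses — are exact.
    """
    n = len(bases)
    intervals: set[tuple[int, int]] = set()
    end_d = _semiglobal_end_dists(adapter, bases)
    for j in range(1, n + 1):
        if end_d[j] <= budget:
            window = _best_window(adapter, bases, j, budget, from_start=False)
            if window:
                intervals.add(window)
    start_d = _semiglobal_end_dists(adapter[::-1], bases[::-1])
    for jr in range(1, n + 1):
        if start_d[jr] <= budget:
            s = n - jr
            window = _best_window(adapter, bases, s, budget, from_start=True)
            if window:
                intervals.add(window)
    return sorted(intervals)


def find_adapter_matches(read: Read, spec: AdapterSpec) -> list[tuple[int, int]]:
    """All admissible adapter matches as 0-based half-open read intervals.

    Internal matches of the full adapter are enumerated exhaustively; among
    the anchored flank overlaps only the longest admissible one is reported
    (shorter overlaps are nested inside it and never change the trim result).
    """
    bases = read.bases
    adapter = spec.sequence
    n, m = len(bases), len(adapter)
    budget_full = math.floor(spec.error_rate * m)

    if spec.allow_indels:
        matches = set(_internal_matches_edit(bases, adapter, budget_full))
    else:
        matches = set()
        for s in range(n - m + 1):
            if _hamming_within(bases[s : s + m], adapter, budget_full) >= 0:
                matches.add((s, s + m))

    for k in range(min(m, n), spec.min_overlap - 1, -1):
        budget = math.floor(spec.error_rate * k)
        if spec.direction == "right":
            a, b, interval = adapter[:k], bases[n - k :], (n - k, n)
        else:
            a, b, interval = adapter[m - k :], bases[:k], (0, k)
        d = (
            _levenshtein_within(a, b, budget)
            if spec.allow_indels
            else _hamming_within(a, b, budget)
        )
        if d >= 0:
            matches.add(interval)
            break

    return sorted(matches)


def adapter_trim(read: Read, spec: AdapterSpec) -> TrimResult:
    """Trim the longest subsequence containing any match plus the rest of the
    read in the trimming direction; unmatched reads pass through unchanged."""
    matches = find_adapter_matches(read, spec)
    if not matches:
        return TrimResult(read, 0, False)
    if spec.direction == "right":
        cut = min(start for start, _ in matches)
        new = replace(read, bases=read.bases[:cut], quals=read.quals[:cut])
    else:
        cut = max(end for _, end in matches)
        new = replace(read, bases=read.bases[cut:], quals=read.quals[cut:])
    return TrimResult(new, len(read) - len(new), True)


def quality_trim_5p(read: Read, threshold: int) -> TrimResult:
    """Remove the maximal 5' prefix in which every base scores below
    ``threshold``; stops at the first base at or above it."""
    i = 0
    while i < len(read.quals) and read.quals[i] < threshold:
        i += 1
    if i == 0:
        return TrimResult(read, 0, False)
    new = replace(read, bases=read.bases[i:], quals=read.quals[i:])
    return TrimResult(new, i, True)


def fixed_trim(read: Read, n: int, end: str) -> TrimResult:
    """Remove ``min(n, L)`` bases from the named end ('5p' or '3p')."""
    if end not in ("5p", "3p"):
        raise ValueError("end must be '5p' or '3p'")
    if n < 0:
        raise ValueError("n must be >= 0")
    cut = min(n, len(read))
    if cut == 0:
        return TrimResult(read, 0, False)
    if end == "5p":
        new = replace(read, bases=read.bases[cut:], quals=read.quals[cut:])
    else:
        new = replace(read, bases=read.bases[:-cut], quals=read.quals[:-cut])
    return TrimResult(new, cut, True)
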