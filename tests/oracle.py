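"""Brute-force alignment oracle for adapter trimming.

Enumerates every internal offset and every flank overlap literally and
applies the keep-rule (smallest match start for right-trimming, largest
match end for left-trimming).  Deliberately naive and independent of the
package implementation.
"""

import math


def _hamming(a, b):
    return sum(x != y for x, y in zip(a, b))


def _lev(a, b):
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(
                min(
                    prev[j - 1] + (0 if ca == cb else 1),
                    prev[j] + 1,
                    cur[j - 1] + 1,
                )
            )
        prev = cur
    return prev[-1]


def oracle_candidates(bases, adapter, error_rate, min_overlap, direction,
                      allow_indels=False):
    """Every admissible (start, end) interval, fully enumerated."""
    n, m = len(bases), len(adapter)
    dist = _lev if allow_indels else _hamming
    cands = []
    budget_full = math.floor(error_rate * m)
    if allow_indels:
        # every substring within the edit-distance budget
        for s in range(n):
            for e in range(s + 1, n + 1):
                if _lev(adapter, bases[s:e]) <= budget_full:
                    cands.append((s, e))
    else:
        for s in range(n - m + 1):
            if _hamming(bases[s : s + m], adapter) <= budget_full:
                cands.append((s, s + m))
    for k in range(min_overlap, min(m, n) + 1):
        budget = math.floor(error_rate * k)
        if direction == "right":
            a, b, iv = adapter[:k], bases[n - k :], (n - k, n)
        else:
            a, b, iv = adapter[m - k :], bases[:k], (0, k)
        if dist(a, b) <= budget:
            cands.append(iv)
    return cands


def oracle_trim(bases, adapter, error_rate, min_overlap, direction,
                allow_indels=False):
    """Retained base string after applying the keep-rule literally."""
    cands = oracle_candidates(
        bases, adapter, error_rate, min_overlap, direction, allow_indels
    )
    if not cands:
        return bases
    if direction == "right":
        return bases[: min(s for s, _ in cands)]
    return bases[max(e for _, e in cands) :]
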