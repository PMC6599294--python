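"""Diagnostic statistics on a random sample of reads.

All statistics (per-cycle base composition and quality, read-length
histogram, top k-mers, top duplicated sequences) are computed on one shared
uniform sample drawn by single-pass reservoir sampling, so arbitrarily large
files can be profiled with bounded memory.  Reports are serialised as
canonical JSON and, optionally, a static HTML page with the same numbers.
"""

from __future__ import annotations

import json
import random
from collections import Counter
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fastq_io import ChunkSpec, Read, detect_file_encoding, read_chunks

__all__ = [
    "sample_reads",
    "base_composition",
    "per_cycle_quality",
    "kmer_table",
    "duplicate_table",
    "length_histogram",
    "qc_report",
]

SCHEMA_VERSION = 1
BASES = ("A", "C", "G", "T", "N")


def sample_reads(path, n: int, seed: int) -> list[Read]:
    """Uniform sample of ``n`` reads without replacement, in file order.

    Single-pass reservoir sampling; files with at most ``n`` reads are
    returned whole.  Deterministic for a fixed seed.
    """
    if n < 1:
        raise ValueError("sample size must be >= 1")
    rng = random.Random(seed)
    reservoir: list[Read] = []
    positions: list[int] = []
    i = 0
    for chunk in read_chunks(path):
        for read in chunk:
            if i < n:
                reservoir.append(read)
                positions.append(i)
            else:
                j = rng.randrange(i + 1)
                if j < n:
                    reservoir[j] = read
                    positions[j] = i
            i += 1
    order = sorted(range(len(reservoir)), key=positions.__getitem__)
    return [reservoir[k] for k in order]


def base_composition(reads: Sequence[Read]) -> pd.DataFrame:
    """Fraction of A/C/G/T/N at each cycle (1-based index).

    The denominator at cycle ``c`` counts only reads of length >= ``c``, so
    every populated row sums to 1.
    """
    if not reads:
        raise ValueError("at least one read required")
    max_len = max(len(r) for r in reads)
    counts = {b: np.zeros(max_len, dtype=np.int64) for b in BASES}
    for read in reads:
        for c, base in enumerate(read.bases):
            counts[base][c] += 1
    table = pd.DataFrame(counts, index=pd.RangeIndex(1, max_len + 1, name="cycle"))
    totals = table.sum(axis=1)
    return table.div(totals.replace(0, np.nan), axis=0)


def per_cycle_quality(reads: Sequence[Read]) -> pd.DataFrame:
    """Mean and quartiles of Phred scores at each cycle (1-based index)."""
    if not reads:
        raise ValueError("at least one read required")
    max_len = max(len(r) for r in reads)
    per_cycle: list[list[int]] = [[] for _ in range(max_len)]
    for read in reads:
        for c, q in enumerate(read.quals):
            per_cycle[c].append(q)
    rows = []
    for cycle_quals in per_cycle:
        if cycle_quals:
            arr = np.asarray(cycle_quals)
            q25, med, q75 = np.percentile(arr, [25, 50, 75])
            rows.append((arr.mean(), q25, med, q75))
        else:
            rows.append((np.nan,) * 4)
    return pd.DataFrame(
        rows,
        columns=["mean", "q25", "median", "q75"],
        index=pd.RangeIndex(1, max_len + 1, name="cycle"),
    )


def kmer_table(reads: Sequence[Read], k: int = 8, top: int = 20) -> list[tuple[str, int]]:
    """Most frequent k-mers over all overlapping N-free windows.

    Sorted by descending count, ties broken lexicographically.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: Counter[str] = Counter()
    for read in reads:
        bases = read.bases
        for i in range(len(bases) - k + 1):
            kmer = bases[i : i + k]
            if "N" not in kmer:
                counts[kmer] += 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:top]


def duplicate_table(reads: Sequence[Read], top: int = 20) -> list[tuple[str, int]]:
    """Sequences occurring at least twice in the sample, with their counts."""
    counts = Counter(read.bases for read in reads)
    dups = [(seq, c) for seq, c in counts.items() if c >= 2]
    dups.sort(key=lambda kv: (-kv[1], kv[0]))
    return dups[:top]


def length_histogram(reads: Sequence[Read]) -> list[tuple[int, int]]:
    """(length, count) pairs sorted by length."""
    counts = Counter(len(r) for r in reads)
    return sorted(counts.items())


def qc_report(
    path,
    n: int = 100000,
    seed: int = 0,
    k: int = 8,
    top: int = 20,
    json_out=None,
    html_out=None,
) -> dict:
    """Run all diagnostics on one shared sample; optionally serialise.

    Returns the report as a plain dict; JSON output is canonical
    (sorted keys) and therefore byte-identical across runs for a fixed
    (path, n, seed, k, top).
    """
    sample = sample_reads(path, n, seed)
    if not sample:
        raise ValueError(f"no reads in {path}")
    enc = detect_file_encoding(path)
    comp = base_composition(sample)
    qual = per_cycle_quality(sample)
    report = {
        "schema_version": SCHEMA_VERSION,
        "sample_size": len(sample),
        "encoding": enc.to_dict() if enc else None,
        "per_cycle_base_freq": {
            "cycle": [int(c) for c in comp.index],
            **{b: [None if np.isnan(v) else round(float(v), 10) for v in comp[b]] for b in BASES},
        },
        "per_cycle_quality": {
            "cycle": [int(c) for c in qual.index],
            **{
                col: [None if np.isnan(v) else round(float(v), 10) for v in qual[col]]
                for col in qual.columns
            },
        },
        "length_histogram": [[int(l), int(c)] for l, c in length_histogram(sample)],
        "top_kmers": [[km, int(c)] for km, c in kmer_table(sample, k=k, top=top)],
        "top_duplicates": [[s, int(c)] for s, c in duplicate_table(sample, top=top)],
    }
    if json_out is not None:
        with open(json_out, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
    if html_out is not None:
        with open(html_out, "w") as fh:
            fh.write(_render_html(report, comp, qual))
    return report


def _render_html(report: dict, comp: pd.DataFrame, qual: pd.DataFrame) -> str:
    kmers = pd.DataFrame(report["top_kmers"], columns=["kmer", "count"])
    dups = pd.DataFrame(report["top_duplicates"], columns=["sequence", "count"])
    lengths = pd.DataFrame(report["length_histogram"], columns=["length", "count"])
    sections = [
        ("Per-cycle base composition", comp.round(4).to_html()),
        ("Per-cycle quality", qual.round(2).to_html()),
        ("Read length histogram", lengths.to_html(index=False)),
        ("Top k-mers", kmers.to_html(index=False)),
        ("Duplicated sequences", dups.to_html(index=False)),
    ]
    body = "\n".join(f"<h2>{title}</h2>\n{table}" for title, table in sections)
    return (
        "<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
        "<title>fqclean QC report</title></head><body>\n"
        f"<h1>fqclean QC report</h1>\n"
        f"<p>Sample size: {report['sample_size']}; "
        f"encoding: {report['encoding']}</p>\n{body}\n</body></html>\n"
    )
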