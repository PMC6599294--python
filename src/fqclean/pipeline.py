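"""Chunk-wise single-read and paired-end processing.

Each chunk of reads passes the configured trimmers first, then the removal
filters, so length and quality filters judge the post-trim read.  For
paired-end input the two mates are processed independently and only pairs
surviving in *both* mates are written, keeping the outputs rank-synchronised.
Deduplication state and the pair-intersection bookkeeping persist across
chunks, so results are independent of the chunk size.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from itertools import zip_longest
from typing import Callable, Iterable, Optional, Sequence

from . import filters as _filters
from . import trimmers as _trimmers
from .fastq_io import (
    ChunkSpec,
    EncodingInfo,
    FastqWriter,
    Read,
    detect_file_encoding,
    read_chunks,
)
from .trimmers import AdapterSpec

__all__ = [
    "PipelineConfig",
    "RunSummary",
    "PairSyncError",
    "process_sr",
    "process_pe",
    "build_summary",
    "normalize_read_id",
    "TRIMMER_STEPS",
    "FILTER_STEPS",
    "DEFAULT_STEP_ORDER",
]

log = logging.getLogger("fqclean")

TRIMMER_STEPS = ("cut_5p", "cut_3p", "quality_trim_5p", "adapter_trim")
FILTER_STEPS = (
    "filter_n",
    "filter_length",
    "filter_complexity",
    "filter_mean_quality",
    "dedup",
)
#: Order used when a config is assembled from flat CLI flags.
DEFAULT_STEP_ORDER = TRIMMER_STEPS + FILTER_STEPS

#: Filter step -> removal-reason key used in summaries and logs.
FILTER_REASONS = {
    "filter_n": "n",
    "filter_length": "length",
    "filter_complexity": "complexity",
    "filter_mean_quality": "meanq",
    "dedup": "duplicate",
}


class PairSyncError(ValueError):
    """Raised when paired input files disagree in length or identifiers."""


@dataclass(slots=True)
class PipelineConfig:
    """Ordered processing steps plus streaming parameters.

    ``steps`` is a list of ``(name, params)`` pairs; names must be unique and
    drawn from :data:`TRIMMER_STEPS` and :data:`FILTER_STEPS`.  Trimmers are
    applied before filters regardless of interleaving, each group in the
    declared order.
    """

    steps: list[tuple[str, dict]] = field(default_factory=list)
    chunk_size: int = 10000
    seed: int = 0
    gzip_output: bool = False

    def __post_init__(self) -> None:
        names = [name for name, _ in self.steps]
        if len(names) != len(set(names)):
            raise ValueError("step names must be unique")
        known = set(TRIMMER_STEPS) | set(FILTER_STEPS)
        unknown = set(names) - known
        if unknown:
            raise ValueError(f"unknown step(s): {sorted(unknown)}")
        if self.chunk_size < 1:
            raise ValueError("chunk_size must be >= 1")

    def trimmer_steps(self) -> list[tuple[str, dict]]:
        return [s for s in self.steps if s[0] in TRIMMER_STEPS]

    def filter_steps(self) -> list[tuple[str, dict]]:
        return [s for s in self.steps if s[0] in FILTER_STEPS]


@dataclass(slots=True)
class RunSummary:
    """Exact per-filter and per-trimmer accounting for one run."""

    input_reads: int = 0
    output_reads: int = 0
    removed: dict = field(default_factory=dict)
    bases_trimmed: dict = field(default_factory=dict)
    encoding: Optional[EncodingInfo] = None
    mates: Optional[dict] = None

    def check(self) -> None:
        if self.input_reads != self.output_reads + sum(self.removed.values()):
            raise AssertionError(
                f"accounting violated: {self.input_reads} input != "
                f"{self.output_reads} output + {sum(self.removed.values())} removed"
            )

    def to_dict(self) -> dict:
        return {
            "input_reads": self.input_reads,
            "output_reads": self.output_reads,
            "removed": dict(sorted(self.removed.items())),
            "bases_trimmed": dict(sorted(self.bases_trimmed.items())),
            "encoding": self.encoding.to_dict() if self.encoding else None,
            "mates": self.mates,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def normalize_read_id(read_id: str) -> str:
    """Identifier stem shared by both mates: first token, no /1 or /2 suffix."""
    stem = read_id.split(None, 1)[0] if read_id else read_id
    if stem.endswith(("/1", "/2")):
        stem = stem[:-2]
    return stem


def _bind_trimmer(name: str, params: dict) -> Callable[[Read], _trimmers.TrimResult]:
    if name == "cut_5p":
        n = int(params["n"])
        return lambda r: _trimmers.fixed_trim(r, n, "5p")
    if name == "cut_3p":
        n = int(params["n"])
        return lambda r: _trimmers.fixed_trim(r, n, "3p")
    if name == "quality_trim_5p":
        threshold = int(params["threshold"])
        return lambda r: _trimmers.quality_trim_5p(r, threshold)
    if name == "adapter_trim":
        adapters: Sequence[AdapterSpec] = params["adapters"]

        def _trim_all(read: Read) -> _trimmers.TrimResult:
            removed = 0
            matched = False
            for spec in adapters:
                res = _trimmers.adapter_trim(read, spec)
                read = res.read
                removed += res.bases_removed
                matched = matched or res.matched
            return _trimmers.TrimResult(read, removed, matched)

        return _trim_all
    raise ValueError(f"unknown trimmer {name!r}")


def _bind_filter(name: str, params: dict) -> Callable[[Read], _filters.FilterDecision]:
    if name == "filter_n":
        max_n = int(params.get("max_n", 0))
        return lambda r: _filters.filter_n(r, max_n)
    if name == "filter_length":
        min_length = int(params.get("min_length", 0))
        return lambda r: _filters.filter_length(r, min_length)
    if name == "filter_complexity":
        threshold = float(params.get("threshold", 0.5))
        return lambda r: _filters.filter_complexity(r, threshold)
    if name == "filter_mean_quality":
        min_q = float(params.get("min_q", 20.0))
        return lambda r: _filters.filter_mean_quality(r, min_q)
    if name == "dedup":
        return _filters.Deduplicator().check
    raise ValueError(f"unknown filter {name!r}")


class _MateProcessor:
    """Bound trimmers/filters plus running tallies for one input stream."""

    def __init__(self, cfg: PipelineConfig):
        self.trimmers = [(n, _bind_trimmer(n, p)) for n, p in cfg.trimmer_steps()]
        self.filters = [(n, _bind_filter(n, p)) for n, p in cfg.filter_steps()]
        self.input_reads = 0
        self.removed: dict[str, int] = {}
        self.bases_trimmed: dict[str, int] = {name: 0 for name, _ in self.trimmers}

    def process_chunk(self, chunk: list[Read]) -> list[Read]:
        survivors = []
        self.input_reads += len(chunk)
        for read in chunk:
            for name, trim in self.trimmers:
                res = trim(read)
                self.bases_trimmed[name] += res.bases_removed
                read = res.read
            keep = True
            for _, predicate in self.filters:
                decision = predicate(read)
                if not decision.keep:
                    self.removed[decision.reason] = (
                        self.removed.get(decision.reason, 0) + 1
                    )
                    keep = False
                    break
            if keep:
                survivors.append(read)
        return survivors

    def summary(self, output_reads: int, encoding=None) -> RunSummary:
        return RunSummary(
            input_reads=self.input_reads,
            output_reads=output_reads,
            removed=dict(self.removed),
            bases_trimmed=dict(self.bases_trimmed),
            encoding=encoding,
        )


def build_summary(
    tallies: Iterable[RunSummary],
    encoding: Optional[EncodingInfo] = None,
    mates: Optional[dict] = None,
) -> RunSummary:
    """Sum per-chunk (or per-mate) tallies into one exact summary."""
    total = RunSummary(encoding=encoding, mates=mates)
    for t in tallies:
        total.input_reads += t.input_reads
        total.output_reads += t.output_reads
        for k, v in t.removed.items():
            total.removed[k] = total.removed.get(k, 0) + v
        for k, v in t.bases_trimmed.items():
            total.bases_trimmed[k] = total.bases_trimmed.get(k, 0) + v
        if total.encoding is None:
            total.encoding = t.encoding
    total.check()
    return total


def process_sr(input_path, output_path, cfg: PipelineConfig) -> RunSummary:
    """Stream a single-read file through the configured steps."""
    enc = detect_file_encoding(input_path)
    proc = _MateProcessor(cfg)
    written = 0
    with FastqWriter(output_path, compress=cfg.gzip_output) as out:
        for i, chunk in enumerate(
            read_chunks(input_path, ChunkSpec(cfg.chunk_size), enc)
        ):
            survivors = proc.process_chunk(chunk)
            out.write(survivors)
            written += len(survivors)
            log.info("chunk %d: %d reads in, %d kept", i, len(chunk), len(survivors))
    summary = proc.summary(written, encoding=enc)
    summary.check()
    return summary


def process_pe(
    in1,
    in2,
    out1,
    out2,
    cfg: PipelineConfig,
    cfg_mate2: Optional[PipelineConfig] = None,
) -> RunSummary:
    """Two-step paired processing: per-mate SR processing, then intersection.

    Inputs must be rank-aligned with matching identifier stems; the outputs
    contain exactly the pairs whose reads survive in both mates, in input
    order.  ``cfg_mate2`` optionally overrides the steps for mate 2 (e.g. a
    different adapter); streaming parameters come from ``cfg``.
    """
    enc1 = detect_file_encoding(in1)
    enc2 = detect_file_encoding(in2)
    proc1 = _MateProcessor(cfg)
    proc2 = _MateProcessor(cfg_mate2 if cfg_mate2 is not None else cfg)
    spec = ChunkSpec(cfg.chunk_size)
    written = 0
    pair_lost = {1: 0, 2: 0}
    rank = 0
    with FastqWriter(out1, compress=cfg.gzip_output) as w1, FastqWriter(
        out2, compress=cfg.gzip_output
    ) as w2:
        for i, (chunk1, chunk2) in enumerate(
            zip_longest(read_chunks(in1, spec, enc1), read_chunks(in2, spec, enc2))
        ):
            if chunk1 is None or chunk2 is None or len(chunk1) != len(chunk2):
                raise PairSyncError("paired input files have unequal read counts")
            for r1, r2 in zip(chunk1, chunk2):
                rank += 1
                if normalize_read_id(r1.id) != normalize_read_id(r2.id):
                    raise PairSyncError(
                        f"identifier mismatch at read {rank}: "
                        f"{r1.id!r} vs {r2.id!r}"
                    )
            s1 = proc1.process_chunk(chunk1)
            s2 = proc2.process_chunk(chunk2)
            ids1 = {normalize_read_id(r.id) for r in s1}
            ids2 = {normalize_read_id(r.id) for r in s2}
            common = ids1 & ids2
            keep1 = [r for r in s1 if normalize_read_id(r.id) in common]
            keep2 = [r for r in s2 if normalize_read_id(r.id) in common]
            pair_lost[1] += len(s1) - len(keep1)
            pair_lost[2] += len(s2) - len(keep2)
            w1.write(keep1)
            w2.write(keep2)
            written += len(keep1) + len(keep2)
            log.info(
                "chunk %d: %d pairs in, %d pairs kept", i, len(chunk1), len(keep1)
            )

    mates = {}
    per_mate_summaries = []
    for mate, proc, enc in ((1, proc1, enc1), (2, proc2, enc2)):
        removed = dict(proc.removed)
        if pair_lost[mate]:
            removed["pair"] = pair_lost[mate]
        s = RunSummary(
            input_reads=proc.input_reads,
            output_reads=written // 2,
            removed=removed,
            bases_trimmed=dict(proc.bases_trimmed),
            encoding=enc,
        )
        s.check()
        per_mate_summaries.append(s)
        mates[f"mate{mate}"] = s.to_dict()
    summary = build_summary(per_mate_summaries, encoding=enc1, mates=mates)
    return summary
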