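"""Trimming-quality scoring against simulator ground truth.

Reads are classified at the read level into a 2x2 confusion table:

* TP — contaminated read trimmed exactly to its known insert length;
* TN — non-contaminated read left untrimmed;
* FP — over-trimming (a read cut shorter than its true length, or any
  trimming of a non-contaminated read);
* FN — under-trimming (a contaminated read left longer than its true length).

Reads absent from the trimmed output (e.g. removed by a length filter) count
as trimmed to length 0.  From the class proportions the standard derived
statistics are computed: sensitivity SEN = TP/(TP+FN), specificity
SPC = TN/(FP+TN), positive and negative predictive values PPV = TP/(TP+FP),
NPV = TN/(TN+FN), and the Matthews correlation coefficient
MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
Any statistic with a zero denominator is reported as missing, never as 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .fastq_io import read_chunks
from .pipeline import normalize_read_id

__all__ = [
    "TruthRecord",
    "EvalCounts",
    "EvalStats",
    "TruthMismatchError",
    "classify_read",
    "aggregate_counts",
    "compute_stats",
    "average_stats",
    "load_truth",
    "trimmed_lengths",
    "evaluate_files",
]


class TruthMismatchError(KeyError):
    """A trimmed read's identifier does not appear in the truth table."""


@dataclass(frozen=True, slots=True)
class TruthRecord:
    read_id: str
    mate: int
    true_length: int
    contaminated: bool


@dataclass(frozen=True, slots=True)
class EvalCounts:
    """TP/TN/FP/FN as proportions of all evaluated reads."""

    tp: float
    tn: float
    fp: float
    fn: float

    def __post_init__(self) -> None:
        total = self.tp + self.tn + self.fp + self.fn
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"proportions must sum to 1, got {total}")
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("proportions must be non-negative")

    @classmethod
    def from_labels(cls, labels: Sequence[str]) -> "EvalCounts":
        if not labels:
            raise ValueError("at least one classification required")
        n = len(labels)
        return cls(
            tp=labels.count("TP") / n,
            tn=labels.count("TN") / n,
            fp=labels.count("FP") / n,
            fn=labels.count("FN") / n,
        )

    def to_dict(self) -> dict:
        return {"TP": self.tp, "TN": self.tn, "FP": self.fp, "FN": self.fn}


@dataclass(frozen=True, slots=True)
class EvalStats:
    sen: Optional[float]
    spc: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    mcc: Optional[float]

    def to_dict(self) -> dict:
        return {
            "SEN": self.sen,
            "SPC": self.spc,
            "PPV": self.ppv,
            "NPV": self.npv,
            "MCC": self.mcc,
        }


def classify_read(
    trimmed_length: int,
    truth: TruthRecord,
    read_length: int,
    tolerance: int = 0,
) -> str:
    """Assign one read to TP, TN, FP or FN.

    ``tolerance`` widens "exactly the true length" to +/- that many bases
    (default 0, the strict definition).
    """
    if not 0 <= trimmed_length <= read_length:
        raise ValueError(
            f"trimmed_length {trimmed_length} outside [0, {read_length}]"
        )
    if truth.contaminated:
        if abs(trimmed_length - truth.true_length) <= tolerance:
            return "TP"
        if trimmed_length < truth.true_length:
            return "FP"
        return "FN"
    # non-contaminated: true length equals the read length
    if trimmed_length >= read_length - tolerance:
        return "TN"
    return "FP"


def aggregate_counts(
    labels: Sequence[str],
    mates: Optional[Sequence[int]] = None,
) -> tuple[EvalCounts, Optional[dict[int, EvalCounts]]]:
    """Overall proportions, plus per-mate proportions when mates are given."""
    overall = EvalCounts.from_labels(labels)
    if mates is None:
        return overall, None
    if len(mates) != len(labels):
        raise ValueError("labels and mates must align")
    per_mate = {}
    for mate in sorted(set(mates)):
        sub = [lab for lab, m in zip(labels, mates) if m == mate]
        per_mate[mate] = EvalCounts.from_labels(sub)
    return overall, per_mate


def _ratio(num: float, den: float) -> Optional[float]:
    return num / den if den > 0 else None


def compute_stats(c: EvalCounts) -> EvalStats:
    """Derived statistics; zero-denominator ratios are missing (None)."""
    denom_sq = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    mcc = (
        (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom_sq) if denom_sq > 0 else None
    )
    return EvalStats(
        sen=_ratio(c.tp, c.tp + c.fn),
        spc=_ratio(c.tn, c.fp + c.tn),
        ppv=_ratio(c.tp, c.tp + c.fp),
        npv=_ratio(c.tn, c.tn + c.fn),
        mcc=mcc,
    )


def average_stats(stats: Iterable[EvalStats]) -> EvalStats:
    """Arithmetic mean of each statistic across groups (e.g. the two mates).

    A statistic missing in any group is missing in the average.
    """
    stats = list(stats)
    fields = ("sen", "spc", "ppv", "npv", "mcc")
    values = {}
    for f in fields:
        vals = [getattr(s, f) for s in stats]
        values[f] = None if any(v is None for v in vals) else sum(vals) / len(vals)
    return EvalStats(**values)


def load_truth(path) -> list[TruthRecord]:
    """Read a simulator truth table (TSV)."""
    df = pd.read_csv(path, sep="\t")
    return [
        TruthRecord(
            read_id=str(row.read_id),
            mate=int(row.mate),
            true_length=int(row.true_length),
            contaminated=bool(row.contaminated),
        )
        for row in df.itertuples()
    ]


def trimmed_lengths(path, known_ids: Optional[set[str]] = None) -> dict[str, int]:
    """Map identifier stems to post-trim read lengths for one FASTQ file."""
    lengths: dict[str, int] = {}
    for chunk in read_chunks(path):
        for read in chunk:
            stem = normalize_read_id(read.id)
            if known_ids is not None and stem not in known_ids:
                raise TruthMismatchError(
                    f"read {read.id!r} is not in the truth table"
                )
            lengths[stem] = len(read)
    return lengths


def evaluate_files(
    truth_path,
    trimmed1,
    trimmed2=None,
    read_length: int = 100,
    tolerance: int = 0,
) -> dict:
    """Score trimmed FASTQ file(s) against a truth table.

    Returns a dict with overall and per-mate counts and statistics and the
    mate-averaged statistics (when both mates are evaluated).
    """
    truth = load_truth(truth_path)
    known = {t.read_id for t in truth}
    lengths = {1: trimmed_lengths(trimmed1, known)}
    mates_present = [1]
    if trimmed2 is not None:
        lengths[2] = trimmed_lengths(trimmed2, known)
        mates_present.append(2)

    labels, mates = [], []
    for rec in truth:
        if rec.mate not in lengths:
            continue
        trimmed = lengths[rec.mate].get(rec.read_id, 0)
        labels.append(classify_read(trimmed, rec, read_length, tolerance))
        mates.append(rec.mate)
    if not labels:
        raise ValueError("no reads evaluated")

    overall, per_mate = aggregate_counts(labels, mates)
    result = {
        "read_length": read_length,
        "tolerance": tolerance,
        "n_reads": len(labels),
        "counts": overall.to_dict(),
        "stats": compute_stats(overall).to_dict(),
        "per_mate": {
            str(m): {
                "counts": c.to_dict(),
                "stats": compute_stats(c).to_dict(),
            }
            for m, c in per_mate.items()
        },
    }
    if len(mates_present) == 2:
        result["stats_mate_averaged"] = average_stats(
            compute_stats(per_mate[m]) for m in (1, 2)
        ).to_dict()
    return result


def write_eval_json(result: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(result, fh, indent=2, sort_keys=True)
        fh.write("\n")
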