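"""Truth-annotated paired-end read simulation with adapter read-through.

Fragments are drawn from a reference with Normal(frag_mean, frag_sd) lengths.
When a fragment is shorter than the read length the sequencer reads through
into the ligated adapter, so the read's 3' end carries an adapter prefix
(and, if the adapter itself is exhausted, random bases).  Every read is
recorded in a truth table with its known non-contaminated length, which is
what trimming benchmarks score against.

Sequencing noise is a parametric i.i.d. substitution model — a deliberate
simplification of empirically trained error profiles; see the methods note
for what this does and does not emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .fastq_io import Read

__all__ = [
    "SimConfig",
    "TRUSEQ_ADAPTER_R1",
    "TRUSEQ_ADAPTER_R2",
    "random_reference",
    "load_fasta_reference",
    "simulate_pe",
    "write_truth_table",
]

# Canonical Illumina TruSeq adapter pair (R1 / R2 read-through sequences).
TRUSEQ_ADAPTER_R1 = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"
TRUSEQ_ADAPTER_R2 = "AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGT"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(slots=True)
class SimConfig:
    """Simulation parameters.

    Defaults model a typical short-insert Illumina paired-end library:
    100 bp reads at 10-fold coverage, fragment lengths Normal(200, 70).
    """

    read_length: int = 100
    coverage: float = 10.0
    frag_mean: float = 200.0
    frag_sd: float = 70.0
    adapter1: str = TRUSEQ_ADAPTER_R1
    adapter2: str = TRUSEQ_ADAPTER_R2
    sub_error_rate: float = 0.005
    quality_model: str = "constant"  # or "linear-decay"
    base_quality: int = 35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.frag_sd < 0:
            raise ValueError("frag_sd must be >= 0")
        if not 0.0 <= self.sub_error_rate < 1.0:
            raise ValueError("sub_error_rate must be in [0, 1)")
        if self.quality_model not in ("constant", "linear-decay"):
            raise ValueError("quality_model must be 'constant' or 'linear-decay'")
        for name in ("adapter1", "adapter2"):
            seq = getattr(self, name)
            if not seq or set(seq) - set("ACGT"):
                raise ValueError(f"{name} must be a non-empty ACGT string")


def random_reference(length: int, gc: float = 0.5, seed: int = 0) -> str:
    """i.i.d. random reference with the given GC fraction."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(np.array(list("ACGT")), size=length, p=probs))


def load_fasta_reference(path) -> str:
    """Concatenated upper-case sequence of all records in a FASTA file."""
    from Bio import SeqIO

    parts = [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")]
    if not parts:
        raise ValueError(f"no FASTA records in {path}")
    return "".join(parts)


def _quality_profile(cfg: SimConfig) -> tuple[int, ...]:
    if cfg.quality_model == "constant":
        return (cfg.base_quality,) * cfg.read_length
    # linear decay from base_quality down to base_quality - 10 along the read
    lo = max(2, cfg.base_quality - 10)
    return tuple(
        int(round(cfg.base_quality - (cfg.base_quality - lo) * i / max(1, cfg.read_length - 1)))
        for i in range(cfg.read_length)
    )


def _apply_substitutions(bases: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0:
        return bases
    arr = list(bases)
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        alternatives = [b for b in "ACGT" if b != arr[i]]
        arr[i] = alternatives[rng.integers(3)]
    return "".join(arr)


def _build_mate(
    template: str,
    adapter: str,
    cfg: SimConfig,
    rng: np.random.Generator,
    err_rng: np.random.Generator,
) -> str:
    """Read of exactly ``read_length`` bases: fragment, then adapter, then pad."""
    rl = cfg.read_length
    bases = template[:rl]
    if len(bases) < rl:
        bases += adapter[: rl - len(bases)]
    if len(bases) < rl:
        pad = rng.choice(np.array(list("ACGT")), size=rl - len(bases))
        bases += "".join(pad)
    return _apply_substitutions(bases, cfg.sub_error_rate, err_rng)


def simulate_pe(
    reference: str, cfg: SimConfig
) -> tuple[list[Read], list[Read], pd.DataFrame]:
    """Simulate N = round(coverage * ref_len / (2 * read_length)) read pairs.

    Returns mate-1 reads, mate-2 reads and a truth table with one row per
    read (columns: read_id, mate, true_length, contaminated).  Mate 1 reads
    the fragment's forward strand into ``adapter1``; mate 2 reads the reverse
    complement into ``adapter2``.
    """
    ref_len = len(reference)
    if ref_len < cfg.read_length:
        raise ValueError("reference must be at least read_length long")
    # separate streams so the fragment layout is identical across error rates
    rng = np.random.default_rng(cfg.seed)
    err_rng = np.random.default_rng([cfg.seed, 1])
    n_pairs = int(round(cfg.coverage * ref_len / (2.0 * cfg.read_length)))
    quals = _quality_profile(cfg)

    reads1: list[Read] = []
    reads2: list[Read] = []
    truth_rows = []
    frag_lens = np.rint(rng.normal(cfg.frag_mean, cfg.frag_sd, size=n_pairs)).astype(int)
    frag_lens = np.clip(frag_lens, 1, ref_len)
    for i in range(n_pairs):
        frag_len = int(frag_lens[i])
        start = int(rng.integers(0, ref_len - frag_len + 1))
        fragment = reference[start : start + frag_len]
        rid = f"sim_{i:06d}"
        true_length = min(frag_len, cfg.read_length)
        contaminated = frag_len < cfg.read_length
        bases1 = _build_mate(fragment, cfg.adapter1, cfg, rng, err_rng)
        bases2 = _build_mate(_revcomp(fragment), cfg.adapter2, cfg, rng, err_rng)
        reads1.append(Read(id=f"{rid}/1", bases=bases1, quals=quals))
        reads2.append(Read(id=f"{rid}/2", bases=bases2, quals=quals))
        for mate in (1, 2):
            truth_rows.append((rid, mate, true_length, contaminated))

    truth = pd.DataFrame(
        truth_rows, columns=["read_id", "mate", "true_length", "contaminated"]
    )
    return reads1, reads2, truth


def write_truth_table(truth: pd.DataFrame, path) -> None:
    """Write the truth table as a tab-separated file."""
    truth.to_csv(path, sep="\t", index=False)
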