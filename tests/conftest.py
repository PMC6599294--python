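import random

import pytest

from fqclean.fastq_io import Read, write_reads


def make_read(bases, q=30, rid="r1", comment=None, quals=None):
    if quals is None:
        quals = (q,) * len(bases)
    return Read(id=rid, bases=bases, quals=tuple(quals), comment=comment)


def random_read(rng: random.Random, rid, length, alphabet="ACGT", qlo=2, qhi=40):
    bases = "".join(rng.choice(alphabet) for _ in range(length))
    quals = tuple(rng.randint(qlo, qhi) for _ in range(length))
    return Read(id=rid, bases=bases, quals=quals)


def random_reads(seed, n, length=50, alphabet="ACGT", prefix="r"):
    rng = random.Random(seed)
    return [random_read(rng, f"{prefix}{i}", length, alphabet) for i in range(n)]


ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"  # TruSeq R1


def mixed_reads(seed, n, length=60, prefix="m"):
    """Reads exercising every filter: Ns, duplicates, short reads, adapter
    contamination and a spread of qualities."""
    rng = random.Random(seed)
    reads = []
    for i in range(n):
        kind = rng.random()
        if kind < 0.1:
            bases = "".join(rng.choice("ACGTN") for _ in range(length))
        elif kind < 0.2:
            bases = "A" * length  # low complexity + duplicates
        elif kind < 0.3:
            bases = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 15)))
        elif kind < 0.45:  # adapter contamination
            cut = rng.randint(5, length - 5)
            bases = (
                "".join(rng.choice("ACGT") for _ in range(cut))
                + ADAPTER[: length - cut]
            )
        else:
            bases = "".join(rng.choice("ACGT") for _ in range(length))
        quals = tuple(rng.choice([3, 12, 30, 38]) for _ in range(len(bases)))
        reads.append(make_read(bases, quals=quals, rid=f"{prefix}{i}"))
    return reads


@pytest.fixture
def fastq_file(tmp_path):
    """Factory writing reads to a temporary FASTQ file."""

    counter = {"n": 0}

    def _write(reads, name=None, compress=False):
        counter["n"] += 1
        name = name or f"reads{counter['n']}.fastq"
        path = tmp_path / name
        write_reads(reads, path, compress=compress)
        return path

    return _write
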