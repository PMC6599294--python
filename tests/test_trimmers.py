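import random

import pytest

from fqclean.trimmers import (
    AdapterSpec,
    adapter_trim,
    find_adapter_matches,
    fixed_trim,
    quality_trim_5p,
)

from .conftest import make_read
from .oracle import oracle_trim

ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"  # 33 nt


def _nonmatching(rng, length, adapter, error_rate, min_overlap):
    """Random sequence with no admissible match for the given adapter."""
    while True:
        bases = "".join(rng.choice("ACGT") for _ in range(length))
        if (
            oracle_trim(bases, adapter, error_rate, min_overlap, "right") == bases
            and oracle_trim(bases, adapter, error_rate, min_overlap, "left") == bases
        ):
            return bases


class TestAdapterSpec:
    def test_validation(self):
        with pytest.raises(ValueError):
            AdapterSpec("")
        with pytest.raises(ValueError):
            AdapterSpec("ACGT", error_rate=0.5)
        with pytest.raises(ValueError):
            AdapterSpec("ACGT", min_overlap=5)
        with pytest.raises(ValueError):
            AdapterSpec("ACGT", direction="up")


class TestFindMatches:
    def test_no_adapter_like_substring(self):
        rng = random.Random(0)
        bases = _nonmatching(rng, 60, ADAPTER, 0.1, 5)
        assert find_adapter_matches(make_read(bases), AdapterSpec(ADAPTER)) == []

    def test_internal_match_after_insert(self):
        rng = random.Random(1)
        insert = _nonmatching(rng, 50, ADAPTER, 0.0, 5)
        tail = "".join(rng.choice("ACGT") for _ in range(17))
        read = make_read(insert + ADAPTER + tail)
        spec = AdapterSpec(ADAPTER, error_rate=0.0)
        matches = find_adapter_matches(read, spec)
        assert (50, 83) in matches
        assert min(s for s, _ in matches) == 50

    def test_flank_overlap_at_3p_end(self):
        rng = random.Random(2)
        insert = _nonmatching(rng, 45, ADAPTER, 0.0, 5)
        read = make_read(insert + ADAPTER[:5])
        spec = AdapterSpec(ADAPTER, error_rate=0.0, min_overlap=5)
        assert find_adapter_matches(read, spec) == [(45, 50)]

    def test_overlap_below_min_overlap_ignored(self):
        rng = random.Random(3)
        insert = _nonmatching(rng, 45, ADAPTER, 0.0, 5)
        read = make_read(insert + ADAPTER[:4])
        spec = AdapterSpec(ADAPTER, error_rate=0.0, min_overlap=5)
        # the 4-base flank may not anchor; any match must come from elsewhere
        assert (46, 50) not in find_adapter_matches(read, spec)

    def test_mismatch_budget_is_floor_of_rate_times_length(self):
        insert = "C" * 40
        contaminated = ADAPTER[:10]
        mutated = "T" + contaminated[1:]  # 1 mismatch on a 10-base overlap
        read = make_read(insert + mutated)
        assert find_adapter_matches(
            make_read(insert + mutated), AdapterSpec(ADAPTER, error_rate=0.1)
        ) == [(40, 50)]  # floor(0.1*10) = 1 mismatch allowed
        assert (
            find_adapter_matches(read, AdapterSpec(ADAPTER, error_rate=0.09)) == []
        )  # floor(0.09*10) = 0

    def test_n_in_read_never_matches(self):
        insert = "C" * 40
        read = make_read(insert + "N" + ADAPTER[1:6])
        # N creates a mismatch on every overlap; at error 0 nothing matches
        assert find_adapter_matches(read, AdapterSpec(ADAPTER, error_rate=0.0)) == []


class TestAdapterTrim:
    def test_no_match_returns_read_unchanged(self):
        rng = random.Random(4)
        read = make_read(_nonmatching(rng, 60, ADAPTER, 0.1, 5))
        res = adapter_trim(read, AdapterSpec(ADAPTER))
        assert res.read == read and res.bases_removed == 0 and not res.matched

    def test_read_equal_to_adapter_trims_to_empty(self):
        res = adapter_trim(make_read(ADAPTER), AdapterSpec(ADAPTER, error_rate=0.0))
        assert len(res.read) == 0
        assert res.bases_removed == len(ADAPTER)
        assert res.matched

    def test_multiple_matches_left_trims_through_rightmost(self):
        rng = random.Random(5)
        while True:
            pre = "".join(rng.choice("ACGT") for _ in range(10))
            mid = "".join(rng.choice("ACGT") for _ in range(17))
            tail = "".join(rng.choice("ACGT") for _ in range(7))
            bases = pre + ADAPTER + mid + ADAPTER + tail
            expected = oracle_trim(bases, ADAPTER, 0.0, 5, "left")
            if expected == tail:  # no spurious flank match at the 5' end
                break
        read = make_read(bases)
        res = adapter_trim(read, AdapterSpec(ADAPTER, error_rate=0.0, direction="left"))
        assert res.read.bases == tail
        assert res.bases_removed == 93

    def test_qualities_trimmed_in_lockstep(self):
        read = make_read("C" * 40 + ADAPTER[:10], quals=tuple(range(50)))
        res = adapter_trim(read, AdapterSpec(ADAPTER, error_rate=0.0))
        assert res.read.quals == tuple(range(40))
        assert len(res.read.bases) == len(res.read.quals)

    def test_idempotent_for_exact_adapters(self):
        rng = random.Random(6)
        spec = AdapterSpec(ADAPTER, error_rate=0.0)
        for _ in range(20):
            insert = "".join(rng.choice("ACGT") for _ in range(40))
            read = make_read(insert + ADAPTER[: rng.randint(5, 33)])
            once = adapter_trim(read, spec).read
            assert adapter_trim(once, spec).read == once

    @pytest.mark.parametrize("allow_indels", [False, True])
    @pytest.mark.parametrize("direction", ["right", "left"])
    def test_matches_bruteforce_oracle(self, direction, allow_indels):
        rng = random.Random(7 if allow_indels else 8)
        n_cases = 60 if allow_indels else 250
        for i in range(n_cases):
            m = rng.randint(6, 16)
            adapter = "".join(rng.choice("ACGT") for _ in range(m))
            length = rng.randint(10, 40 if allow_indels else 70)
            bases = list(rng.choice("ACGTN" if i % 5 == 0 else "ACGT")
                         for _ in range(length))
            if rng.random() < 0.7:  # plant a (possibly mutated) adapter copy
                copy = list(adapter)
                for _ in range(rng.randint(0, 2)):
                    copy[rng.randrange(m)] = rng.choice("ACGT")
                pos = rng.randint(0, max(0, length - m))
                bases[pos : pos + m] = copy
            bases = "".join(bases)[:length]
            error_rate = rng.choice([0.0, 0.1, 0.2])
            spec = AdapterSpec(
                adapter,
                error_rate=error_rate,
                min_overlap=min(5, m),
                allow_indels=allow_indels,
                direction=direction,
            )
            expected = oracle_trim(
                bases, adapter, error_rate, spec.min_overlap, direction, allow_indels
            )
            got = adapter_trim(make_read(bases), spec).read.bases
            assert got == expected, (bases, adapter, error_rate, direction)

    def test_retained_prefix_has_no_remaining_full_match(self):
        rng = random.Random(9)
        spec = AdapterSpec(ADAPTER, error_rate=0.1)
        for i in range(50):
            bases = "".join(rng.choice("ACGT") for _ in range(80))
            pos = rng.randint(0, 47)
            bases = bases[:pos] + ADAPTER + bases[pos + 33 :]
            kept = adapter_trim(make_read(bases), spec).read.bases
            assert find_adapter_matches(make_read(kept), spec) == [] or all(
                end > len(kept) for _, end in find_adapter_matches(make_read(kept), spec)
            )


class TestQualityTrim5p:
    def test_removes_leading_low_quality(self):
        read = make_read("ACGT", quals=(2, 2, 30, 30))
        res = quality_trim_5p(read, 20)
        assert res.read.bases == "GT" and res.bases_removed == 2 and res.matched

    def test_all_above_threshold_unchanged(self):
        read = make_read("ACGT", q=30)
        res = quality_trim_5p(read, 20)
        assert res.read == read and not res.matched

    def test_all_below_threshold_empties_read(self):
        read = make_read("ACGT", q=2)
        assert len(quality_trim_5p(read, 20).read) == 0

    def test_stops_at_first_high_base(self):
        read = make_read("ACGTA", quals=(2, 30, 2, 2, 2))
        assert quality_trim_5p(read, 20).read.bases == "CGTA"


class TestFixedTrim:
    def test_3p_keeps_5p_portion(self):
        read = make_read("".join("ACGT"[i % 4] for i in range(36)))
        res = fixed_trim(read, 5, "3p")
        assert len(res.read) == 31
        assert res.read.bases == read.bases[:31]

    def test_n_exceeding_length_empties_read(self):
        assert len(fixed_trim(make_read("ACGT"), 10, "5p").read) == 0

    def test_n_zero_unchanged(self):
        read = make_read("ACGT")
        res = fixed_trim(read, 0, "3p")
        assert res.read == read and res.bases_removed == 0

    def test_5p_removes_from_start(self):
        read = make_read("AACCGGTT", quals=tuple(range(8)))
        res = fixed_trim(read, 3, "5p")
        assert res.read.bases == "CGGTT" and res.read.quals == (3, 4, 5, 6, 7)
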