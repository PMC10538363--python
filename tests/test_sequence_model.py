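import pytest
from hypothesis import given, strategies as st

from conftest import dna
from minitig.sequence_model import (
    CountingParams,
    InvalidSequenceError,
    Orientation,
    OverlapError,
    Rk128,
    acgt_runs,
    canonical,
    canonical_str,
    kmers_of,
    merge_overlap,
    normalize_cycle,
    occ,
    occ_cn,
    reverse_complement,
    rk128_hash,
    validate_dna,
)


@pytest.mark.parametrize("s,expected", [
    ("ACG", "CGT"),
    ("AT", "AT"),          # palindrome fixed point
    ("AAAACGT", "ACGTTTT"),
])
def test_reverse_complement_examples(s, expected):
    assert reverse_complement(s) == expected


@given(dna)
def test_reverse_complement_involution(s):
    assert reverse_complement(reverse_complement(s)) == s


def test_validate_dna_rejects_non_acgt():
    with pytest.raises(InvalidSequenceError):
        validate_dna("ACGN")
    with pytest.raises(InvalidSequenceError):
        validate_dna("")
    assert validate_dna("ACGT") == "ACGT"


@pytest.mark.parametrize("s,rep,orient", [
    ("TTT", "AAA", Orientation.REVERSE),
    ("AAA", "AAA", Orientation.FORWARD),
    ("AT", "AT", Orientation.FORWARD),  # palindrome
])
def test_canonical_examples(s, rep, orient):
    assert canonical(s) == (rep, orient)


@given(dna)
def test_canonical_strand_invariant(s):
    assert canonical(s)[0] == canonical(reverse_complement(s))[0]
    assert canonical_str(s) == canonical(s)[0]


@pytest.mark.parametrize("x,y,t,expected", [
    ("ACGT", "CGTA", 3, "ACGTA"),
    ("AC", "AC", 2, "AC"),     # full-overlap identity
    ("ACG", "CGA", 2, "ACGA"),
])
def test_merge_overlap_examples(x, y, t, expected):
    assert merge_overlap(x, y, t) == expected


def test_merge_overlap_mismatch():
    with pytest.raises(OverlapError):
        merge_overlap("ACGT", "GGTA", 3)


@given(dna, st.data())
def test_merge_overlap_preserves_kmers(x, data):
    t = data.draw(st.integers(min_value=1, max_value=len(x)))
    suffix = data.draw(st.text(alphabet="ACGT", max_size=10))
    y = x[len(x) - t:] + suffix
    merged = merge_overlap(x, y, t)
    for k in range(1, t + 2):
        merged_kmers = set(kmers_of(merged, k))
        assert set(kmers_of(x, k)) <= merged_kmers
        assert set(kmers_of(y, k)) <= merged_kmers
        assert merged_kmers == set(kmers_of(x, k)) | set(kmers_of(y, k))


@pytest.mark.parametrize("x,R,expected", [
    ("ACG", ["ACG"], 1),
    ("ACG", ["CGTCGT"], 2),   # two occurrences of the reverse complement
    ("AT", ["ATA"], 1),       # palindrome counted once per occurrence
    ("AA", ["AAAA"], 3),      # overlapping occurrences; rc TT absent
])
def test_occ_cn_examples(x, R, expected):
    assert occ_cn(x, R) == expected


@given(dna, st.lists(dna, max_size=5))
def test_occ_cn_strand_symmetric(x, R):
    assert occ_cn(x, R) == occ_cn(reverse_complement(x), R)


def test_occ_counts_overlapping():
    assert occ("AA", ["AAA", "AA"]) == 3


def test_counting_params_validation():
    with pytest.raises(ValueError):
        CountingParams(1)
    with pytest.raises(ValueError):
        CountingParams(5, 0)
    assert CountingParams(5).canonical_mode


def test_acgt_runs_splits_and_drops():
    assert acgt_runs("ACGTNNACG", min_len=4) == ["ACGT"]
    assert acgt_runs("acgtnACG") == ["ACGT", "ACG"]
    assert acgt_runs("NNN") == []


def test_normalize_cycle_rotation_and_strand():
    core = "ACGTT"
    forms = {normalize_cycle(core[i:] + core[:i]) for i in range(len(core))}
    rc = reverse_complement(core)
    forms |= {normalize_cycle(rc[i:] + rc[:i]) for i in range(len(rc))}
    assert len(forms) == 1


class TestRk128:
    def test_equal_strings_equal_hash(self):
        assert rk128_hash("ACGTACG") == rk128_hash("ACGTACG")

    def test_distinct_base_codes(self):
        assert len({rk128_hash(c) for c in "ACGT"}) == 4

    def test_roll_matches_scratch(self):
        rk = Rk128(4)
        h = rk.hash("ACGT")
        assert rk.roll(h, "A", "A") == rk.hash("CGTA")
        s = "ACGTTGCAACGGTT"
        h = rk.hash(s[:4])
        for i in range(1, len(s) - 3):
            h = rk.roll(h, s[i - 1], s[i + 3])
            assert h == rk.hash(s[i:i + 4])

    def test_length_check(self):
        with pytest.raises(ValueError):
            Rk128(4).hash("ACG")
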