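import collections

import pytest
from hypothesis import given, strategies as st

from minitig.minimizer_hashing import MinimizerParams, choose_m, window_minimizers
from minitig.read_splitting import (
    NO_COLOR,
    ExtendedSegment,
    assign_bucket,
    extend_segments,
    read_bucket_file,
    split_into_buckets,
    split_records,
    split_sequence,
    write_bucket_file,
)
from minitig.reference_oracle import check_split_groups
from minitig.sequence_model import merge_overlap
from minitig.synthetic_fixtures import random_genome, sample_reads

TOY = MinimizerParams(4, 2, "rank", canonical=False)


def test_split_toy_example():
    # window minima of "ACGTACGT" under the rank hash: [1,6,11,1,1,6]
    segs = split_sequence("ACGTACGT", TOY)
    assert [s.text for s in segs] == ["ACG", "CGT", "GTA", "TACG", "CGT"]
    assert [(s.start, s.end) for s in segs] == [
        (0, 3), (1, 4), (2, 5), (3, 7), (5, 8)]
    assert [s.minimizer for s in segs] == [1, 6, 11, 1, 6]


def test_split_single_distinct_mmer():
    segs = split_sequence("AAAAAA", TOY)
    assert len(segs) == 1 and segs[0].text == "AAAAAA"


def test_split_read_of_length_k():
    # both (k-1)-mers grouped by their (possibly equal) window minima
    read = "ACGT"
    segs = split_sequence(read, TOY)
    mins = window_minimizers(read, TOY)
    assert len(segs) == (1 if mins[0] == mins[1] else 2)
    assert segs[0].start == 0 and segs[-1].end == len(read)


def test_split_short_read_skipped():
    assert split_sequence("ACG", TOY) == []


@given(st.text(alphabet="ACGT", min_size=6, max_size=120))
def test_split_invariants(read):
    params = MinimizerParams(5, 2)
    segs = split_sequence(read, params)
    assert segs[0].start == 0 and segs[-1].end == len(read)
    for a, b in zip(segs, segs[1:]):
        assert a.end - b.start == params.k - 2  # overlap of exactly k-2
    for seg in segs:
        assert seg.end - seg.start >= params.k - 1
        assert set(window_minimizers(seg.text, params)) == {seg.minimizer}


def test_extend_segments_links_toy():
    read = "ACGTACGT"
    segs = split_sequence(read, TOY)
    ext = extend_segments(read, segs)
    assert ext[0].text == "ACGT" and not ext[0].left_link and ext[0].right_link
    assert ext[1].text == "ACGTA" and ext[1].left_link and ext[1].right_link
    assert ext[0].text[-4:] == ext[1].text[:4]  # k-character overlap


def test_extend_single_segment_read():
    read = "AAAAAA"
    (ext,) = extend_segments(read, split_sequence(read, TOY))
    assert not ext.left_link and not ext.right_link and ext.text == read


@given(st.text(alphabet="ACGT", min_size=6, max_size=150))
def test_extended_segments_reconstruct_read(read):
    params = MinimizerParams(5, 2)
    ext = extend_segments(read, split_sequence(read, params))
    merged = ext[0].text
    for seg in ext[1:]:
        merged = merge_overlap(merged, seg.text, params.k)
    assert merged == read


def test_assign_bucket():
    assert assign_bucket(12345, 1) == 0
    assert assign_bucket(12345, 64) == assign_bucket(12345, 64)
    with pytest.raises(ValueError):
        assign_bucket(1, 48)


def test_assign_bucket_near_uniform(rng):
    n = 64
    counts = collections.Counter(
        assign_bucket(rng.getrandbits(64), n) for _ in range(64000))
    expect = 64000 / n
    chi2 = sum((c - expect) ** 2 / expect for c in counts.values())
    assert chi2 < 2 * n  # loose sanity bound, ~n-1 dof


def test_split_records_skips_short_and_ambiguous():
    params = MinimizerParams(5, 2)
    recs = [("a", "ACG"), ("b", "ACGTACGTNNNACGTA"), ("c", "NNNN")]
    segs = list(split_records(recs, params))
    text = "".join(s.text for s in segs)
    assert "N" not in text and segs


def test_bucket_file_roundtrip(tmp_path):
    segs = [ExtendedSegment("ACGTACG", True, False, 123456789, 2),
            ExtendedSegment("TTTT", False, True, 42, NO_COLOR)]
    p = tmp_path / "b.mtb"
    write_bucket_file(p, segs)
    assert read_bucket_file(p) == segs


def test_grouping_properties_on_reads():
    """The three structural splitting properties, brute-forced."""
    genome = random_genome(700, 5)
    reads = [s for _, s in sample_reads(genome, 60, 3.0, 0.5, 0.005, seed=5)]
    params = MinimizerParams(9, choose_m(9))
    groups: dict[int, list[str]] = {}
    for seg in split_records(((f"r{i}", s) for i, s in enumerate(reads)), params):
        groups.setdefault(seg.minimizer, []).append(seg.text)
    assert check_split_groups(groups, reads, params) == []


def test_split_into_buckets_routes_by_minimizer():
    params = MinimizerParams(7, 3)
    genome = random_genome(400, 9)
    buckets = split_into_buckets([([("g", genome)], NO_COLOR)], params, 16)
    for b, segs in buckets.items():
        for seg in segs:
            assert assign_bucket(seg.minimizer, 16) == b
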