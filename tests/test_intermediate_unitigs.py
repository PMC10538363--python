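import pytest

from minitig.intermediate_unitigs import (
    SIDE_LEFT,
    SIDE_RIGHT,
    count_bucket,
    extend_unitig,
    filter_abundance,
    process_bucket,
)
from minitig.minimizer_hashing import MinimizerParams, choose_m
from minitig.read_splitting import NO_COLOR, ExtendedSegment, split_into_buckets
from minitig.sequence_model import CountingParams, canonical_str, occ_cn
from minitig.synthetic_fixtures import random_genome


def seg(text, left=False, right=False, mini=0, color=NO_COLOR):
    return ExtendedSegment(text, left, right, mini, color)


class TestCountBucket:
    def test_linking_character_flags(self):
        # "ACGT" with a right link: only the last k-mer covers the link
        table = count_bucket([seg("ACGT", right=True)],
                             CountingParams(3, 1, canonical_mode=False))
        assert table.entries["ACG"].abundance == 1
        assert not table.entries["ACG"].has_link
        e = table.entries["CGT"]
        assert e.abundance == 1 and e.right_blocked and not e.left_blocked

    def test_canonical_folding(self):
        table = count_bucket([seg("ACG"), seg("CGT")], CountingParams(3))
        assert set(table.entries) == {"ACG"}
        assert table.entries["ACG"].abundance == 2

    def test_link_side_follows_canonical_orientation(self):
        # TTT has a left link; canonically it is AAA with the link on the right
        table = count_bucket([seg("TTTA", left=True)], CountingParams(3))
        e = table.entries["AAA"]
        assert e.right_blocked and not e.left_blocked

    def test_abundance_matches_brute_force(self):
        texts = [random_genome(30, s) for s in range(6)]
        params = CountingParams(5)
        table = count_bucket([seg(t) for t in texts], params)
        for key, e in table.entries.items():
            assert e.abundance == occ_cn(key, texts)

    def test_colors_accumulate(self):
        table = count_bucket([seg("ACGT", color=0), seg("ACGT", color=2)],
                             CountingParams(3))
        assert table.entries["ACG"].colors == {0, 2}


def test_filter_abundance():
    params = CountingParams(3, canonical_mode=False)
    table = count_bucket([seg("ACGT"), seg("ACGA")], params)
    assert set(filter_abundance(table, 1).entries) == {"ACG", "CGT", "CGA"}
    table2 = count_bucket([seg("ACGT"), seg("ACGA")], params)
    assert set(filter_abundance(table2, 2).entries) == {"ACG"}


class TestExtendUnitig:
    def _table(self, kmers, params, flags=()):
        table = count_bucket([seg(km) for km in kmers], params)
        for km, side in flags:
            e = table.entries[table.fold(km)[2]]
            if side == "L":
                e.left_blocked = True
            else:
                e.right_blocked = True
        return table

    def test_chained_unique_extensions(self):
        params = CountingParams(3, canonical_mode=False)
        table = self._table(["ACG", "CGT", "GTA"], params)
        unitig, records = extend_unitig("ACG", table)
        assert unitig.text == "ACGTA" and records == []
        assert all(e.used for e in table.entries.values())

    def test_branch_stops_extension(self):
        params = CountingParams(3, canonical_mode=False)
        table = self._table(["ACG", "CGT", "CGA"], params)
        unitig, records = extend_unitig("ACG", table)
        assert unitig.text == "ACG" and records == []

    def test_link_stop_emits_record(self):
        params = CountingParams(3, canonical_mode=False)
        table = self._table(["ACG", "CGT"], params, flags=[("CGT", "R")])
        unitig, records = extend_unitig("ACG", table)
        assert unitig.text == "ACGT" and unitig.right_open
        (rec,) = records
        assert rec.kmer == "CGT" and rec.side == SIDE_RIGHT

    def test_used_seed_rejected(self):
        params = CountingParams(3, canonical_mode=False)
        table = self._table(["ACG"], params)
        extend_unitig("ACG", table)
        with pytest.raises(ValueError):
            extend_unitig("ACG", table)

    def test_cycle_closes_and_normalizes(self):
        params = CountingParams(3, canonical_mode=False)
        table = self._table(["ACG", "CGA", "GAC"], params)
        unitig, records = extend_unitig("ACG", table)
        assert unitig.is_cycle and records == []
        # spelled as least rotation with a k-1 wrap
        assert unitig.text == "ACGAC"

    def test_reverse_complement_foldback_stops(self):
        # CAT's unique continuation is its own reverse complement: stop
        table = self._table(["CAT"], CountingParams(3))
        unitig, records = extend_unitig("ATG", table)
        assert unitig.text == "ATG" and not records


def test_process_bucket_partitions_kmers():
    genome = random_genome(500, 17)
    k = 9
    params = MinimizerParams(k, choose_m(k))
    buckets = split_into_buckets([([("g", genome)], NO_COLOR)], params, 16)
    counting = CountingParams(k)
    seen: dict[str, int] = {}
    for b in sorted(buckets):
        unitigs, records, _ = process_bucket(buckets[b], counting)
        group_seen: dict[int, set] = {}
        for u in unitigs:
            for i in range(len(u.text) - k + 1):
                km = canonical_str(u.text[i:i + k])
                seen[km] = seen.get(km, 0) + 1
    # every genome k-mer is covered; boundary k-mers appear once per group
    genome_kmers = {canonical_str(genome[i:i + k])
                    for i in range(len(genome) - k + 1)}
    assert set(seen) == genome_kmers
    assert all(1 <= n <= 2 for n in seen.values())
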