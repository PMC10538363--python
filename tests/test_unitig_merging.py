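import random

import pytest

from minitig.intermediate_unitigs import (
    SIDE_LEFT,
    SIDE_RIGHT,
    EndpointRecord,
    IntermediateUnitig,
)
from minitig.pipeline import compact
from minitig.sequence_model import Orientation, reverse_complement
from minitig.synthetic_fixtures import random_genome
from minitig.unitig_merging import (
    MergeChain,
    MergeConsistencyError,
    MergeRoundState,
    merge_round,
    pair_endpoints,
    run_merging,
    simulate_worst_case_pair_tries,
    worst_case_pair_join_fraction,
)

F, R = Orientation.FORWARD, Orientation.REVERSE


class TestPairEndpoints:
    def test_direct_join(self):
        recs = [EndpointRecord("ACGG", 1, SIDE_RIGHT, F),
                EndpointRecord("ACGG", 2, SIDE_LEFT, F)]
        (chain,) = pair_endpoints(recs)
        assert chain.items == [(1, F), (2, F)]

    def test_orientation_resolution(self):
        # both ends expose the boundary from their right: flip the second
        recs = [EndpointRecord("ACGG", 1, SIDE_RIGHT, F),
                EndpointRecord("ACGG", 2, SIDE_RIGHT, R)]
        (chain,) = pair_endpoints(recs)
        assert chain.items == [(1, F), (2, R)]

    def test_three_records_is_error(self):
        recs = [EndpointRecord("ACGG", i, SIDE_RIGHT, F) for i in range(3)]
        with pytest.raises(MergeConsistencyError):
            pair_endpoints(recs)

    def test_incompatible_strands_is_error(self):
        recs = [EndpointRecord("ACGG", 1, SIDE_RIGHT, F),
                EndpointRecord("ACGG", 2, SIDE_RIGHT, F)]
        # id2's right end also reads ACGT forward: both unitigs extend
        # leftward of the boundary, which is impossible
        with pytest.raises(MergeConsistencyError):
            pair_endpoints(recs)


def _worst_case_state(n_pairs):
    chains = []
    for i in range(n_pairs):
        base = 3 * i
        chains.append(MergeChain([(base, F), (base + 1, F)]))
        chains.append(MergeChain([(base + 1, F), (base + 2, F)]))
    return MergeRoundState(chains, n_merge_buckets=16)


def test_merge_round_joins_on_shared_end():
    state = _worst_case_state(1)
    rng = random.Random(0)
    for _ in range(50):
        state = merge_round(state, rng)
        if not state.pending:
            break
    assert not state.pending
    (chain,) = state.finalized
    assert [uid for uid, _ in chain.items] == [0, 1, 2]
    assert chain.sealed_left and chain.sealed_right


def test_single_chain_seals_without_partner():
    state = MergeRoundState([MergeChain([(0, F), (1, F)])], n_merge_buckets=4)
    rng = random.Random(3)
    rounds = 0
    while state.pending:
        state = merge_round(state, rng)
        rounds += 1
        assert rounds < 10
    (chain,) = state.finalized
    assert chain.sealed_left and chain.sealed_right and len(chain.items) == 2


def test_single_round_join_probability_is_quarter():
    frac = worst_case_pair_join_fraction(40000, seed=7)
    assert abs(frac - 0.25) < 0.02


def test_expected_tries_is_four():
    mean = simulate_worst_case_pair_tries(40000, seed=7)
    assert abs(mean - 4.0) < 0.1


class TestRunMerging:
    def test_two_unitig_concatenation(self):
        # z1 and z2 share the k=4 boundary "CGTA"
        store = [IntermediateUnitig(1, "ACGTA", right_open=True),
                 IntermediateUnitig(2, "CGTAC", left_open=True)]
        recs = [EndpointRecord("CGTA", 1, SIDE_RIGHT, F),
                EndpointRecord("CGTA", 2, SIDE_LEFT, F)]
        (u,) = run_merging(store, recs, seed=0, k=4, canonical=False)
        assert u.text == "ACGTAC" and not u.is_cycle

    def test_empty_input(self):
        assert run_merging([], [], seed=0, k=4) == []

    def test_orientation_aware_join(self):
        # z2 stored reverse-complemented relative to the junction
        store = [IntermediateUnitig(1, "ACGTA", right_open=True),
                 IntermediateUnitig(2, reverse_complement("CGTAC"),
                                    right_open=True)]
        recs = [EndpointRecord("CGTA", 1, SIDE_RIGHT, F),
                EndpointRecord("CGTA", 2, SIDE_RIGHT, R)]
        (u,) = run_merging(store, recs, seed=0, k=4, canonical=True)
        assert u.text in ("ACGTAC", reverse_complement("ACGTAC"))

    def test_chain_cycle_closes(self):
        # three unitigs forming a circle: A->B->C->A
        store = [IntermediateUnitig(1, "AACGG", left_open=True, right_open=True),
                 IntermediateUnitig(2, "ACGGTA", left_open=True, right_open=True),
                 IntermediateUnitig(3, "GGTAACG", left_open=True, right_open=True)]
        recs = [EndpointRecord("ACGG", 1, SIDE_RIGHT, F),
                EndpointRecord("ACGG", 2, SIDE_LEFT, F),
                EndpointRecord("GGTA", 2, SIDE_RIGHT, F),
                EndpointRecord("GGTA", 3, SIDE_LEFT, F),
                EndpointRecord("AACG", 3, SIDE_RIGHT, F),
                EndpointRecord("AACG", 1, SIDE_LEFT, F)]
        (u,) = run_merging(store, recs, seed=1, k=4, canonical=False)
        assert u.is_cycle
        core = u.text[:-3]
        assert len(core) == 6  # six k-mers in the cycle
        assert u.text[:3] == u.text[-3:]

    def test_seed_independence_end_to_end(self):
        genome = random_genome(3000, 21)
        base = compact([genome], k=11, seed=0)
        for s in range(1, 10):
            assert compact([genome], k=11, seed=s) == base
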