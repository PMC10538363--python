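"""Randomized cross-bucket joining of intermediate unitigs.

Endpoint records are paired by their shared canonical boundary k-mer: each
boundary k-mer straddles exactly two groups, so it appears in exactly two
records, which identify the two intermediate unitigs to be glued there
(overlapping on the full k characters of the boundary k-mer, with one
unitig reverse-complemented when their stored orientations disagree).

The pairs form chains that are concatenated without a union-find structure:
in every round each chain picks one of its *unsealed* ends uniformly at
random and is filed into the merge bucket of that end's terminal unitig id,
leaving a placeholder in the bucket of its other unsealed end. Inside a
bucket, two chains ending at the same unitig id are concatenated; a chain
end that finds neither a partner nor a foreign placeholder provably has no
partner at all and is sealed. Chains whose two ends reach the same unitig
id close into circular unitigs. Two chains that must merge meet with
probability at least 1/4 per round (the worst case: all four ends
unsealed), so the expected number of rounds is constant; the final unitig
set is the same for every random seed — only the round count varies.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .intermediate_unitigs import (
    SIDE_LEFT,
    SIDE_RIGHT,
    EndpointRecord,
    IntermediateUnitig,
)
from .minimizer_hashing import _mix64
from .sequence_model import (
    Orientation,
    merge_overlap,
    normalize_cycle,
    normalize_linear,
    spell_cycle,
    reverse_complement,
)


class MergeConsistencyError(RuntimeError):
    """Endpoint records violate the two-records-per-boundary invariant."""


@dataclass
class MergeChain:
    """An oriented run of intermediate unitigs glued at boundary k-mers.

    ``items`` are (unitig id, orientation-in-chain) pairs; adjacent items
    overlap on the k characters of their shared boundary k-mer. Ends seal
    once they provably have no partner; a chain with both ends sealed is a
    final maximal unitig, a cyclic chain a final circular one.
    """

    items: list[tuple[int, Orientation]]
    sealed_left: bool = False
    sealed_right: bool = False
    is_cycle: bool = False

    def reversed_(self) -> "MergeChain":
        return MergeChain(
            [(uid, o.flipped()) for uid, o in reversed(self.items)],
            self.sealed_right, self.sealed_left, self.is_cycle)

    @property
    def left_id(self) -> int:
        return self.items[0][0]

    @property
    def right_id(self) -> int:
        return self.items[-1][0]


@dataclass
class MergeRoundState:
    """Mutable state of the randomized merging rounds."""

    pending: list[MergeChain]
    finalized: list[MergeChain] = field(default_factory=list)
    round: int = 0
    n_merge_buckets: int = 64


def _junction_reads_canonical(rec: EndpointRecord, junction_right: bool) -> bool:
    """Does the junction k-mer read as its canonical form once the unitig is
    oriented with this record's end facing right (or left)?"""
    flip = (rec.side == SIDE_LEFT) if junction_right else (rec.side == SIDE_RIGHT)
    return (rec.orient is Orientation.FORWARD) != flip


def _close_cycle(chain: MergeChain) -> MergeChain:
    (uid0, o0) = chain.items[0]
    (uid1, o1) = chain.items[-1]
    assert uid0 == uid1
    if o0 is not o1:
        raise MergeConsistencyError(
            f"unitig {uid0} closes on itself with opposite orientations")
    return MergeChain(chain.items[:-1], True, True, is_cycle=True)


def pair_endpoints(records: Sequence[EndpointRecord]) -> list[MergeChain]:
    """Group records by canonical boundary k-mer into two-unitig chains.

    Every canonical end k-mer must occur in exactly two records (it lives in
    exactly two groups); anything else is an internal-consistency error. A
    pair whose two records name the same unitig closes it into a cycle.
    """
    by_kmer: dict[str, list[EndpointRecord]] = {}
    for rec in records:
        by_kmer.setdefault(rec.kmer, []).append(rec)
    chains: list[MergeChain] = []
    for kmer in by_kmer:
        group = by_kmer[kmer]
        if len(group) != 2:
            raise MergeConsistencyError(
                f"boundary k-mer {kmer} has {len(group)} endpoint records, "
                f"expected exactly 2")
        ra, rb = group
        if ra.side == SIDE_LEFT and rb.side == SIDE_RIGHT:
            ra, rb = rb, ra  # avoid needless double flip; required when noncanonical
        o_a = Orientation.REVERSE if ra.side == SIDE_LEFT else Orientation.FORWARD
        o_b = Orientation.REVERSE if rb.side == SIDE_RIGHT else Orientation.FORWARD
        palindrome = kmer == reverse_complement(kmer)
        if not palindrome and (_junction_reads_canonical(ra, True)
                               != _junction_reads_canonical(rb, False)):
            raise MergeConsistencyError(
                f"records at {kmer} expose incompatible strands")
        if ra.unitig_id == rb.unitig_id:
            # both ends of one unitig meet at the same boundary: a circle
            chains.append(MergeChain([(ra.unitig_id, o_a)], True, True,
                                     is_cycle=True))
        else:
            chains.append(MergeChain([(ra.unitig_id, o_a), (rb.unitig_id, o_b)]))
    return chains


def _join(a: MergeChain, b: MergeChain, uid: int) -> MergeChain:
    """Concatenate two chains at their shared terminal unitig id."""
    if a.right_id != uid:
        if b.right_id == uid:
            a, b = b, a  # flip-free arrangement (the only one without RC)
        else:
            a = a.reversed_()
    if b.left_id != uid:
        b = b.reversed_()
    assert a.right_id == uid and b.left_id == uid
    if a.items[-1][1] is not b.items[0][1]:
        raise MergeConsistencyError(
            f"chains disagree on the orientation of unitig {uid}")
    joined = MergeChain(a.items + b.items[1:], a.sealed_left, b.sealed_right)
    if len(joined.items) > 1 and joined.left_id == joined.right_id:
        return _close_cycle(joined)
    return joined


def merge_round(state: MergeRoundState, rng: random.Random) -> MergeRoundState:
    """One randomized round: file, join, seal, retire finished chains."""
    nb = state.n_merge_buckets
    # bucket -> terminal uid -> (chain indices filed here, foreign placeholder owners)
    ends: dict[int, dict[int, list[int]]] = {}
    holders: dict[int, dict[int, set[int]]] = {}
    pending = state.pending
    for ci, chain in enumerate(pending):
        open_ends = [e for e in (0, 1)
                     if not (chain.sealed_left if e == 0 else chain.sealed_right)]
        assert open_ends, "fully sealed chain left in pending"
        pick = open_ends[0] if len(open_ends) == 1 else rng.choice(open_ends)
        key = chain.left_id if pick == 0 else chain.right_id
        b = _mix64(key) % nb
        ends.setdefault(b, {}).setdefault(key, []).append(ci)
        if len(open_ends) == 2:
            other = 1 - pick
            okey = chain.left_id if other == 0 else chain.right_id
            ob = _mix64(okey) % nb
            holders.setdefault(ob, {}).setdefault(okey, set()).add(ci)

    replaced: dict[int, int] = {}  # chain index -> surviving joined index
    new_chains: dict[int, MergeChain] = {}

    def current(ci: int) -> MergeChain:
        return new_chains.get(ci, pending[ci])

    for b in sorted(ends):
        for key in sorted(ends[b]):
            filed = ends[b][key]
            if len(filed) > 2:
                raise MergeConsistencyError(
                    f"unitig id {key} exposed by {len(filed)} chain ends")
            if len(filed) == 2:
                ci, cj = filed
                joined = _join(current(ci), current(cj), key)
                replaced[cj] = ci
                new_chains[ci] = joined
                new_chains.pop(cj, None)
            else:
                (ci,) = filed
                foreign = holders.get(b, {}).get(key, set()) - {ci}
                if not foreign:
                    chain = current(ci)
                    sealed = replace(chain)
                    if chain.left_id == key and not chain.sealed_left:
                        sealed.sealed_left = True
                    else:
                        sealed.sealed_right = True
                    new_chains[ci] = sealed

    next_pending: list[MergeChain] = []
    finalized = list(state.finalized)
    for ci in range(len(pending)):
        if ci in replaced:
            continue
        chain = current(ci)
        if chain.is_cycle or (chain.sealed_left and chain.sealed_right):
            finalized.append(chain)
        else:
            next_pending.append(chain)
    return MergeRoundState(next_pending, finalized, state.round + 1, nb)


@dataclass(frozen=True)
class FinalUnitig:
    """A maximal (possibly circular) unitig with optional per-k-mer colors."""

    text: str
    is_cycle: bool = False
    color_indices: tuple[int, ...] | None = None


def _oriented(u: IntermediateUnitig, orient: Orientation) -> tuple[str, list[int] | None]:
    if orient is Orientation.FORWARD:
        return u.text, u.color_indices
    colors = None if u.color_indices is None else u.color_indices[::-1]
    return reverse_complement(u.text), colors


def _spell_chain(chain: MergeChain, store: dict[int, IntermediateUnitig],
                 k: int) -> tuple[str, list[int] | None]:
    text, colors = _oriented(store[chain.items[0][0]], chain.items[0][1])
    for uid, orient in chain.items[1:]:
        t, c = _oriented(store[uid], orient)
        # adjacent intermediate unitigs share the full boundary k-mer
        text = merge_overlap(text, t, k)
        if colors is not None:
            assert c is not None and colors[-1] == c[0], \
                "boundary k-mer colors disagree between buckets"
            colors = colors + c[1:]
    return text, colors


def _finalize(chain: MergeChain, store: dict[int, IntermediateUnitig], k: int,
              canonical: bool) -> FinalUnitig:
    text, colors = _spell_chain(chain, store, k)
    if chain.is_cycle:
        if text[:k] != text[-k:]:
            raise MergeConsistencyError("cyclic chain fails to close")
        core = text[:-k]
        if colors is not None:
            colors = colors[:-1]
        return _normalized_cycle_unitig(core, colors, k, canonical)
    if canonical:
        norm = normalize_linear(text)
        if norm != text:
            text = norm
            colors = None if colors is None else colors[::-1]
    return FinalUnitig(text, False, None if colors is None else tuple(colors))


def _normalized_cycle_unitig(core: str, colors, k: int,
                             canonical: bool) -> FinalUnitig:
    from .intermediate_unitigs import _min_rotation
    from .sequence_model import canonical_str

    spelled = spell_cycle(core, k)
    by_kmer = None
    if colors is not None:
        by_kmer = {}
        for i in range(len(core)):
            km = spelled[i:i + k]
            by_kmer[canonical_str(km) if canonical else km] = colors[i]
    norm = normalize_cycle(core) if canonical else _min_rotation(core)
    text = spell_cycle(norm, k)
    out_colors = None
    if by_kmer is not None:
        out_colors = tuple(
            by_kmer[canonical_str(text[i:i + k]) if canonical else text[i:i + k]]
            for i in range(len(norm)))
    return FinalUnitig(text, True, out_colors)


def run_merging(unitigs: Iterable[IntermediateUnitig],
                records: Sequence[EndpointRecord], seed: int,
                merge_buckets: int = 64, k: int | None = None,
                canonical: bool = True,
                max_rounds: int = 512) -> list[FinalUnitig]:
    """Merge intermediate unitigs into the final maximal unitig set.

    ``k`` defaults to being inferred from the records' k-mers. The output
    set is independent of ``seed`` (only round counts vary); a round cap
    guards against the statistically unreachable nontermination.
    """
    store = {u.id: u for u in unitigs}
    if k is None:
        if records:
            k = len(records[0].kmer)
        else:
            k = 0
    rng = random.Random(seed)
    chains = pair_endpoints(records)
    in_chain = {uid for c in chains for uid, _ in c.items}

    final: list[FinalUnitig] = []
    for uid, u in store.items():
        if uid in in_chain:
            continue
        if u.is_cycle:
            final.append(FinalUnitig(u.text, True,
                                     None if u.color_indices is None
                                     else tuple(u.color_indices)))
        else:
            text, colors = u.text, u.color_indices
            if canonical:
                norm = normalize_linear(text)
                if norm != text:
                    text, colors = norm, None if colors is None else colors[::-1]
            final.append(FinalUnitig(text, False,
                                     None if colors is None else tuple(colors)))

    state = MergeRoundState([c for c in chains if not c.is_cycle],
                            [c for c in chains if c.is_cycle],
                            n_merge_buckets=merge_buckets)
    while state.pending:
        if state.round >= max_rounds:
            raise RuntimeError(
                f"unitig merging did not converge after {max_rounds} rounds "
                f"({len(state.pending)} chains pending)")
        state = merge_round(state, rng)

    for chain in state.finalized:
        final.append(_finalize(chain, store, k, canonical))
    return final


# ---------------------------------------------------------------------------
# Analysis helpers for the randomized-merge claims.
# ---------------------------------------------------------------------------

def worst_case_pair_join_fraction(n_pairs: int, seed: int,
                                  merge_buckets: int = 64) -> float:
    """Fraction of worst-case chain pairs joined by a single real round.

    Builds ``n_pairs`` independent instances of the worst case — two chains
    sharing one ending, all four ends unsealed — and runs one
    :func:`merge_round`. Each pair joins exactly when both chains pick the
    shared ending, i.e. with probability 1/4.
    """
    pending: list[MergeChain] = []
    F = Orientation.FORWARD
    for i in range(n_pairs):
        base = 3 * i
        pending.append(MergeChain([(base, F), (base + 1, F)]))
        pending.append(MergeChain([(base + 1, F), (base + 2, F)]))
    state = MergeRoundState(pending, n_merge_buckets=merge_buckets)
    state = merge_round(state, random.Random(seed))
    joined = sum(1 for c in state.pending + state.finalized if len(c.items) == 3)
    return joined / n_pairs


def simulate_worst_case_pair_tries(n: int, seed: int) -> float:
    """Mean number of tries until a worst-case pair lands in the same bucket.

    This is the analysis model behind the expected-cost claim: each try,
    both chains independently pick one of their two ends uniformly (ends
    stay unsealed in the modeled worst case) and succeed together with
    probability 1/4, so the try count is geometric with mean 4. Simulated
    explicitly, not sampled from the closed form.
    """
    rng = np.random.default_rng(seed)
    tries = np.zeros(n, dtype=np.int64)
    alive = np.ones(n, dtype=bool)
    while alive.any():
        idx = np.flatnonzero(alive)
        picks = rng.integers(0, 2, size=(idx.size, 2))
        tries[idx] += 1
        success = (picks[:, 0] == 1) & (picks[:, 1] == 1)
        alive[idx[success]] = False
    return float(tries.mean())
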