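"""Per-bucket k-mer counting and intermediate (nonmaximal) unitig extension.

Each bucket holds extended segments whose (k-1)-mers share a minimizer.
Counting scans every k-mer of every segment into a hash table keyed by the
canonical k-mer, tracking abundance, source colors, and — crucially — on
which side a k-mer carries a *linking character*. A k-mer that contains a
linking character straddles a group boundary: its context on that side is
incomplete inside this bucket, so unitig extension must stop there and leave
an endpoint record for the cross-bucket merge step.

Extension follows the both-ways uniqueness rule: a unitig ``z`` grows to the
right only when exactly one k-mer extends ``suf_{k-1}(z)`` forward *and*
that k-mer has exactly one backward extension (which is then necessarily
``suf_k(z)``). Because every queried (k-1)-mer window has this bucket's
minimizer, these neighbor counts equal the global counts, so in-bucket
decisions are globally correct. A candidate whose canonical form is already
part of the growing unitig either closes a cycle (when it equals the first
oriented k-mer) or marks a reverse-complement fold-back, where extension
stops.

For k > 64 the table can be keyed by a 128-bit Rabin-Karp hash of the
canonical k-mer instead of the string itself; hash collisions between
distinct k-mers are detected (counted and logged) but not corrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .coloring import ColorIndex
from .read_splitting import NO_COLOR, ExtendedSegment
from .sequence_model import (
    ALPHABET,
    CountingParams,
    Orientation,
    Rk128,
    canonical_str,
    normalize_cycle,
    spell_cycle,
)

logger = logging.getLogger(__name__)

SIDE_LEFT = "L"
SIDE_RIGHT = "R"


@dataclass
class KmerEntry:
    """One canonical k-mer of a bucket: abundance, link blocks, colors.

    ``left_blocked``/``right_blocked`` are expressed in the canonical
    orientation of the k-mer and mark the side on which some occurrence
    carried a linking character — the side whose context lives in the
    neighboring group.
    """

    text: str
    abundance: int = 0
    left_blocked: bool = False
    right_blocked: bool = False
    used: bool = False
    colors: set[int] = field(default_factory=set)

    @property
    def has_link(self) -> bool:
        return self.left_blocked or self.right_blocked


@dataclass(frozen=True)
class EndpointRecord:
    """A mergeable unitig end: (canonical end k-mer, unitig id, side, strand).

    ``orient`` is FORWARD when the unitig's terminal k-mer, read in the
    unitig's stored orientation, equals the canonical k-mer.
    """

    kmer: str
    unitig_id: int
    side: str  # SIDE_LEFT | SIDE_RIGHT
    orient: Orientation


@dataclass
class IntermediateUnitig:
    """A unitig maximal within one bucket.

    ``left_open``/``right_open`` mark ends whose extension stopped at a
    link-flagged k-mer (and hence have an :class:`EndpointRecord`). Cycles
    are already rotation/strand-normalized linear spellings whose first and
    last k-1 characters coincide.
    """

    id: int
    text: str
    is_cycle: bool = False
    left_open: bool = False
    right_open: bool = False
    color_indices: list[int] | None = None


class KmerTable:
    """Bucket-local map from canonical k-mer to :class:`KmerEntry`.

    In exact mode the key is the canonical k-mer string; in hashed long-k
    mode it is the 128-bit Rabin-Karp hash of that string (collisions
    detected via the stored first-seen text).
    """

    def __init__(self, params: CountingParams, long_k_hash: bool = False):
        self.params = params
        self.canonical = params.canonical_mode
        self.hashed = long_k_hash
        self._rk = Rk128(params.k) if long_k_hash else None
        self.entries: dict[object, KmerEntry] = {}
        self.collisions = 0

    def fold(self, kmer: str) -> tuple[str, bool, object]:
        """(canonical text, is-forward, table key) for an oriented k-mer."""
        if self.canonical:
            text = canonical_str(kmer)
            fwd = text == kmer
        else:
            text, fwd = kmer, True
        key = self._rk.hash(text) if self._rk is not None else text
        return text, fwd, key

    def contains(self, kmer: str) -> bool:
        _, _, key = self.fold(kmer)
        return key in self.entries

    def add_occurrence(self, kmer: str, left_link: bool, right_link: bool,
                       color: int) -> None:
        text, fwd, key = self.fold(kmer)
        entry = self.entries.get(key)
        if entry is None:
            entry = KmerEntry(text)
            self.entries[key] = entry
        elif entry.text != text:
            self.collisions += 1
            logger.warning(
                "128-bit k-mer hash collision: %r vs %r share a key; "
                "the graph around this k-mer may be wrong", entry.text, text)
        entry.abundance += 1
        lb, rb = (left_link, right_link) if fwd else (right_link, left_link)
        entry.left_blocked |= lb
        entry.right_blocked |= rb
        if color != NO_COLOR:
            entry.colors.add(color)


def count_bucket(segments: Iterable[ExtendedSegment], params: CountingParams,
                 long_k_hash: bool = False) -> KmerTable:
    """Count every k-mer of every segment, tracking link sides and colors.

    Consecutive extended segments of one read overlap on k characters, but
    by construction they always sit in different groups, so within a bucket
    each read occurrence of a k-mer is counted exactly once and abundances
    equal the global (canonical) occurrence counts.
    """
    k = params.k
    table = KmerTable(params, long_k_hash)
    for seg in segments:
        t = seg.text
        last = len(t) - k
        for i in range(last + 1):
            table.add_occurrence(
                t[i:i + k],
                seg.left_link and i == 0,
                seg.right_link and i == last,
                seg.color,
            )
    return table


def filter_abundance(table: KmerTable, a: int) -> KmerTable:
    """Keep exactly the entries with abundance >= a (a=1 is the identity)."""
    if a <= 1:
        return table
    table.entries = {key: e for key, e in table.entries.items()
                     if e.abundance >= a}
    return table


def _grow(chars, table: KmerTable, keys_in: set, cur: str, cur_key, cur_fwd: bool,
          rightward: bool) -> tuple[bool, bool]:
    """Extend one direction; returns (stopped_at_link, closed_cycle)."""
    k = table.params.k
    while True:
        entry = table.entries[cur_key]
        if rightward:
            blocked = entry.right_blocked if cur_fwd else entry.left_blocked
        else:
            blocked = entry.left_blocked if cur_fwd else entry.right_blocked
        if blocked:
            return True, False
        if rightward:
            s = cur[1:]
            cands = [c for c in ALPHABET if table.contains(s + c)]
            if len(cands) != 1:
                return False, False
            y = s + cands[0]
            back = [d for d in ALPHABET if table.contains(d + s)]
        else:
            s = cur[:-1]
            cands = [c for c in ALPHABET if table.contains(c + s)]
            if len(cands) != 1:
                return False, False
            y = cands[0] + s
            back = [d for d in ALPHABET if table.contains(s + d)]
        if len(back) != 1:
            return False, False
        ytext, yfwd, ykey = table.fold(y)
        if ykey in keys_in:
            if rightward:
                first = "".join(chars[i] for i in range(k))
                if y == first:
                    return False, True
            else:
                tail = "".join(chars[i] for i in range(len(chars) - k, len(chars)))
                if y == tail:
                    return False, True
            return False, False  # reverse-complement fold-back: stop
        yentry = table.entries[ykey]
        if yentry.used:
            return False, False
        yentry.used = True
        keys_in.add(ykey)
        if rightward:
            chars.append(y[-1])
        else:
            chars.appendleft(y[0])
        cur, cur_key, cur_fwd = y, ykey, yfwd


def extend_unitig(seed_key, table: KmerTable,
                  unitig_id: int = 0) -> tuple[IntermediateUnitig, list[EndpointRecord]]:
    """Grow the in-bucket-maximal unitig containing the (unused) seed k-mer.

    Right extension first, then the symmetric left extension; all consumed
    k-mers are marked used. Ends stopped at a link-flagged k-mer produce
    endpoint records for the merge step; a cycle produces none.
    """
    from collections import deque

    k = table.params.k
    entry = table.entries[seed_key]
    if entry.used:
        raise ValueError("seed k-mer already used")
    entry.used = True
    chars: deque[str] = deque(entry.text)
    keys_in = {seed_key}

    right_open, cycle = _grow(chars, table, keys_in, entry.text, seed_key, True,
                              rightward=True)
    left_open = False
    if not cycle:
        first = "".join(list(chars)[:k])
        ftext, ffwd, fkey = table.fold(first)
        left_open, cycle_l = _grow(chars, table, keys_in, first, fkey, ffwd,
                                   rightward=False)
        cycle = cycle or cycle_l
    text = "".join(chars)
    if cycle:
        core = text[:len(text) - (k - 1)]
        core = normalize_cycle(core) if table.canonical else _min_rotation(core)
        text = spell_cycle(core, k)
        return IntermediateUnitig(unitig_id, text, is_cycle=True), []

    unitig = IntermediateUnitig(unitig_id, text, False, left_open, right_open)
    records: list[EndpointRecord] = []
    if left_open:
        term = text[:k]
        ttext, tfwd, _ = table.fold(term)
        records.append(EndpointRecord(
            ttext, unitig_id, SIDE_LEFT,
            Orientation.FORWARD if tfwd else Orientation.REVERSE))
    if right_open:
        term = text[-k:]
        ttext, tfwd, _ = table.fold(term)
        records.append(EndpointRecord(
            ttext, unitig_id, SIDE_RIGHT,
            Orientation.FORWARD if tfwd else Orientation.REVERSE))
    return unitig, records


def _min_rotation(core: str) -> str:
    doubled = core + core
    return min(doubled[i:i + len(core)] for i in range(len(core)))


def process_group(segments: Sequence[ExtendedSegment], params: CountingParams,
                  start_id: int = 0, color_index: ColorIndex | None = None,
                  long_k_hash: bool = False,
                  ) -> tuple[list[IntermediateUnitig], list[EndpointRecord], int]:
    """Count, filter, and extend the segments of one minimizer group.

    Every filtered k-mer ends up in exactly one intermediate unitig. In
    colored mode each unitig gets one interned color-set index per k-mer.
    Returns (unitigs, endpoint records, detected hash collisions).
    """
    table = filter_abundance(count_bucket(segments, params, long_k_hash), params.a)
    unitigs: list[IntermediateUnitig] = []
    records: list[EndpointRecord] = []
    uid = start_id
    for key in list(table.entries):
        if table.entries[key].used:
            continue
        unitig, recs = extend_unitig(key, table, uid)
        if color_index is not None:
            unitig.color_indices = [
                color_index.intern(table.entries[table.fold(km)[2]].colors)
                for km in (unitig.text[i:i + params.k]
                           for i in range(len(unitig.text) - params.k + 1))
            ]
        unitigs.append(unitig)
        records.extend(recs)
        uid += 1
    return unitigs, records, table.collisions


def process_bucket(segments: Sequence[ExtendedSegment], params: CountingParams,
                   start_id: int = 0, color_index: ColorIndex | None = None,
                   long_k_hash: bool = False,
                   ) -> tuple[list[IntermediateUnitig], list[EndpointRecord], int]:
    """Process one bucket group by group.

    A bucket is only a storage unit: it can hold several minimizer groups
    (all whose minimizers share the bucket's low bits). Counting and
    extension are correct per *group* — a k-mer's context is complete only
    inside its own group — so the bucket's segments are partitioned by
    minimizer first and each group is processed independently.
    """
    groups: dict[int, list[ExtendedSegment]] = {}
    for seg in segments:
        groups.setdefault(seg.minimizer, []).append(seg)
    unitigs: list[IntermediateUnitig] = []
    records: list[EndpointRecord] = []
    collisions = 0
    uid = start_id
    for h in sorted(groups):
        us, recs, n_coll = process_group(groups[h], params, uid,
                                         color_index, long_k_hash)
        unitigs.extend(us)
        records.extend(recs)
        collisions += n_coll
        uid += len(us)
    return unitigs, records, collisions
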