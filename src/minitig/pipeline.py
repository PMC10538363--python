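"""End-to-end graph construction: split, bucket, extend, merge, color.

This is the library driver behind the CLI: it routes extended segments to
buckets, processes every bucket independently (k-mer counting with
abundance filtering, then in-bucket unitig extension), and joins the
intermediate unitigs across buckets with the randomized merge rounds. In
colored mode the per-k-mer color sets are interned into a global color
index during bucket processing and carried through merging as per-unitig
runs of subset indices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .coloring import ColorIndex
from .intermediate_unitigs import EndpointRecord, IntermediateUnitig, process_bucket
from .minimizer_hashing import MinimizerParams, choose_m
from .read_splitting import NO_COLOR, split_into_buckets
from .sequence_model import CountingParams
from .unitig_merging import FinalUnitig, run_merging


@dataclass
class GraphBuild:
    """A built graph: maximal unitigs plus the parameters that define it."""

    unitigs: list[FinalUnitig]
    counting: CountingParams
    minimizers: MinimizerParams
    color_index: ColorIndex | None = None
    hash_collisions: int = 0

    @property
    def colored(self) -> bool:
        return self.color_index is not None

    def as_set(self) -> set[tuple[str, bool]]:
        """Normalized (spelling, is_cycle) set for comparisons."""
        return {(u.text, u.is_cycle) for u in self.unitigs}


def build_graph(inputs: Sequence[Iterable[tuple[str, str]]], k: int,
                a: int = 1, canonical: bool = True, m: int | None = None,
                hash_name: str = "mix64", n_buckets: int = 256,
                merge_buckets: int = 64, seed: int = 0,
                colored: bool = False,
                long_k_hash: bool | None = None) -> GraphBuild:
    """Construct the compacted (optionally colored) de Bruijn graph.

    ``inputs`` is one record stream (iterable of (id, sequence)) per input
    file; in colored mode the stream's position is its color. k-mers are
    represented exactly for k <= 64; beyond that (or when ``long_k_hash``
    forces it) bucket tables are keyed by a 128-bit Rabin-Karp hash.
    The result is independent of ``seed`` as a set; unitigs are reported in
    sorted order so outputs are diffable.
    """
    minimizers = MinimizerParams(k, choose_m(k, m), hash_name, canonical)
    counting = CountingParams(k, a, canonical)
    use_hash = (k > 64) if long_k_hash is None else long_k_hash

    streams = [(records, c if colored else NO_COLOR)
               for c, records in enumerate(inputs)]
    buckets = split_into_buckets(streams, minimizers, n_buckets)

    color_index = ColorIndex() if colored else None
    unitigs: list[IntermediateUnitig] = []
    records: list[EndpointRecord] = []
    collisions = 0
    next_id = 0
    for b in sorted(buckets):
        us, recs, n_coll = process_bucket(
            buckets[b], counting, start_id=next_id,
            color_index=color_index, long_k_hash=use_hash)
        unitigs.extend(us)
        records.extend(recs)
        collisions += n_coll
        next_id += len(us)

    final = run_merging(unitigs, records, seed=seed,
                        merge_buckets=merge_buckets, k=k, canonical=canonical)
    final.sort(key=lambda u: (u.text, u.is_cycle))
    return GraphBuild(final, counting, minimizers, color_index, collisions)


def compact(sequences: Iterable[str], k: int, a: int = 1,
            canonical: bool = True, **kwargs) -> set[tuple[str, bool]]:
    """Convenience wrapper: unitig set of a plain list of sequences."""
    records = [(f"s{i}", s) for i, s in enumerate(sequences)]
    return build_graph([records], k, a, canonical, **kwargs).as_set()
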