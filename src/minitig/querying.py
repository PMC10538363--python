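"""Batch k-mer querying of a built (optionally colored) graph.

Queries reuse the construction machinery: both the graph unitigs and the
query sequences are divided over buckets by minimizer, each bucket is
counted independently, and the per-bucket counters are summed. Each k-mer
occurrence is owned by exactly one bucket — the bucket of its own minimizer
(the smaller of its two window minimizers) — so the bucketed counts equal a
single global membership scan.

Matching is per query *position*: a k-mer occurring twice in a query counts
twice. Uncolored results go to CSV (count and percentage per query),
colored results to JSON Lines with the positive per-color counts.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .coloring import ColorIndex
from .minimizer_hashing import MinimizerParams, kmer_minimizers
from .read_splitting import assign_bucket
from .sequence_model import canonical_str


class QueryParameterError(ValueError):
    """Graph/query parameter mismatch (e.g. different k)."""


@dataclass
class QueryResult:
    """Match counters for one query sequence."""

    query_id: str
    total_kmers: int
    matched: int
    per_color: dict[int, int] | None = None

    @property
    def percent(self) -> float:
        if self.total_kmers == 0:
            return 0.0
        return round(100.0 * self.matched / self.total_kmers, 2)


def build_query_index(graph_sequences: Iterable[tuple[str, Sequence[int] | None]],
                      params: MinimizerParams,
                      n_buckets: int = 256) -> dict[int, dict[str, int]]:
    """Bucketed k-mer index of the graph unitigs.

    Each unitig k-mer is filed under the bucket of its minimizer, mapped to
    its color subset index (-1 when uncolored).
    """
    fold = canonical_str if params.canonical else (lambda s: s)
    k = params.k
    index: dict[int, dict[str, int]] = {}
    for text, color_indices in graph_sequences:
        minis = kmer_minimizers(text, params)
        for i, h in enumerate(minis):
            b = assign_bucket(h, n_buckets)
            idx = -1 if color_indices is None else color_indices[i]
            index.setdefault(b, {})[fold(text[i:i + k])] = idx
    return index


def query_records(graph_sequences: Iterable[tuple[str, Sequence[int] | None]],
                  queries: Sequence[tuple[str, str]],
                  params: MinimizerParams,
                  color_index: ColorIndex | None = None,
                  n_buckets: int = 256) -> list[QueryResult]:
    """Count matched k-mers per query (and per color) against the graph.

    Queries shorter than k are reported with zero totals. Results are
    identical to a single global k-mer table; bucketing only partitions
    the work.
    """
    fold = canonical_str if params.canonical else (lambda s: s)
    k = params.k
    index = build_query_index(graph_sequences, params, n_buckets)
    results: list[QueryResult] = []
    for qid, seq in queries:
        total = max(0, len(seq) - k + 1)
        matched = 0
        per_color: dict[int, int] = {}
        if total > 0 and len(seq) >= k:
            minis = kmer_minimizers(seq, params)
            for i, h in enumerate(minis):
                bucket = index.get(assign_bucket(h, n_buckets))
                if bucket is None:
                    continue
                idx = bucket.get(fold(seq[i:i + k]))
                if idx is None:
                    continue
                matched += 1
                if color_index is not None and idx >= 0:
                    for c in color_index.get(idx):
                        per_color[c] = per_color.get(c, 0) + 1
        results.append(QueryResult(
            qid, total, matched,
            per_color if color_index is not None else None))
    return results


def filter_by_threshold(results: Sequence[QueryResult],
                        threshold: float | None) -> list[QueryResult]:
    """Keep queries whose matched percentage is >= threshold (if given)."""
    if threshold is None:
        return list(results)
    return [r for r in results if r.percent >= threshold]


def write_query_csv(results: Sequence[QueryResult], path,
                    threshold: float | None = None) -> None:
    """CSV report: one line per query with count and percentage (2 decimals)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["query", "total_kmers", "matched", "percent"])
        for r in filter_by_threshold(results, threshold):
            w.writerow([r.query_id, r.total_kmers, r.matched, f"{r.percent:.2f}"])


def write_query_jsonl(results: Sequence[QueryResult], path,
                      threshold: float | None = None) -> None:
    """JSONL report: one object per query; per-color counts only if positive."""
    with open(path, "w") as fh:
        for r in filter_by_threshold(results, threshold):
            obj: dict = {"query": r.query_id, "total_kmers": r.total_kmers,
                         "matched": r.matched}
            if r.per_color:
                obj["colors"] = {str(c): n for c, n in sorted(r.per_color.items())
                                 if n > 0}
            fh.write(json.dumps(obj) + "\n")


def query_batch(graph_fasta, queries_path, threshold: float | None = None,
                k: int | None = None,
                n_buckets: int = 256) -> tuple[list[QueryResult], bool]:
    """File-level entry point: query a written graph with a FASTA/FASTQ batch.

    Reads the graph's metadata sidecar (k, m, hash, canonical mode, colored
    flag) written at build time; a user-supplied ``k`` must match it.
    Returns (results, colored).
    """
    from . import io_cli

    meta = io_cli.read_graph_meta(graph_fasta)
    if k is not None and k != meta["k"]:
        raise QueryParameterError(
            f"graph was built with k={meta['k']}, queried with k={k}")
    params = MinimizerParams(meta["k"], meta["m"], meta["hash_name"],
                             meta["canonical"])
    unitigs = io_cli.read_unitigs(graph_fasta)
    color_index = None
    if meta.get("colored"):
        color_index = io_cli.read_color_map_for(graph_fasta)
    graph_seqs = [(text, runs) for _uid, text, _cyc, runs in unitigs]
    queries = list(io_cli.read_sequences(queries_path))
    results = query_records(graph_seqs, queries, params, color_index, n_buckets)
    return filter_by_threshold(results, threshold), color_index is not None
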