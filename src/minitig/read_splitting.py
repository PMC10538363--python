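"""Split sequences into super-(k-1)-mer segments and route them to buckets.

Each input sequence is cut into maximal runs of consecutive (k-1)-mers that
share the same window minimizer; consecutive segments overlap on k-2
characters. Every segment is then *extended* with the single characters of
the read immediately flanking it (its linking characters), when they exist,
which makes consecutive extended segments overlap on exactly k characters
and makes cross-bucket unitig continuations detectable later. All extended
segments sharing a minimizer form one group; groups are folded into a
smaller fixed number of buckets by the low bits of the minimizer.

A versioned, compressed on-disk bucket format is provided for the CLI
pipeline; the in-memory router is used by the library driver and tests.
"""

from __future__ import annotations

import logging
import struct
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .minimizer_hashing import MinimizerParams, window_minimizers
from .sequence_model import acgt_runs

logger = logging.getLogger(__name__)

NO_COLOR = -1


@dataclass(frozen=True)
class Segment:
    """A super-(k-1)-mer: a read interval whose (k-1)-mers share a minimizer."""

    start: int
    end: int  # half-open
    text: str
    minimizer: int


@dataclass(frozen=True)
class ExtendedSegment:
    """A segment with its linking characters attached.

    ``text`` is ``a + S + b`` where ``a``/``b`` are the read characters
    flanking the segment (dropped, and the corresponding flag cleared, at
    read ends — no sentinel character is ever materialized).
    """

    text: str
    left_link: bool
    right_link: bool
    minimizer: int
    color: int = NO_COLOR


def split_sequence(read: str, params: MinimizerParams) -> list[Segment]:
    """Split ``read`` into super-(k-1)-mer segments in one left-to-right pass.

    Segments cover the read, consecutive segments overlap on exactly k-2
    characters, and within each segment every (k-1)-mer has the same window
    minimizer. Reads shorter than k yield no segments.
    """
    k = params.k
    if len(read) < k:
        return []
    mins = window_minimizers(read, params)
    segments: list[Segment] = []
    run_start = 0
    for i in range(1, len(mins) + 1):
        if i == len(mins) or mins[i] != mins[run_start]:
            start = run_start
            end = (i - 1) + (k - 1)  # end of last (k-1)-mer in the run
            segments.append(Segment(start, end, read[start:end], mins[run_start]))
            run_start = i
    return segments


def extend_segments(read: str, segments: Sequence[Segment],
                    color: int = NO_COLOR) -> list[ExtendedSegment]:
    """Attach linking characters to each segment of ``read``.

    Consecutive outputs overlap on exactly k characters; flags record which
    linking characters are present (absent at read ends).
    """
    out: list[ExtendedSegment] = []
    n = len(read)
    for seg in segments:
        left = seg.start > 0
        right = seg.end < n
        text = read[seg.start - (1 if left else 0): seg.end + (1 if right else 0)]
        out.append(ExtendedSegment(text, left, right, seg.minimizer, color))
    return out


def assign_bucket(h: int, n_buckets: int) -> int:
    """Deterministic minimizer -> bucket map (low bits of the hash value)."""
    if n_buckets < 1 or n_buckets & (n_buckets - 1):
        raise ValueError(f"n_buckets must be a power of two >= 1, got {n_buckets}")
    return h & (n_buckets - 1)


def split_records(records: Iterable[tuple[str, str]], params: MinimizerParams,
                  color: int = NO_COLOR) -> Iterator[ExtendedSegment]:
    """Extended segments of a record stream, splitting at ambiguous bases.

    Each record is (id, sequence); sequences are upper-cased and split at
    non-ACGT characters into maximal runs, runs shorter than k are dropped.
    Records shorter than k are counted and logged, not errors.
    """
    skipped = 0
    for _rid, seq in records:
        any_run = False
        for run in acgt_runs(seq, min_len=params.k):
            any_run = True
            segs = split_sequence(run, params)
            yield from extend_segments(run, segs, color)
        if not any_run:
            skipped += 1
    if skipped:
        logger.info("skipped %d records shorter than k=%d", skipped, params.k)


def split_into_buckets(inputs: Iterable[tuple[Iterable[tuple[str, str]], int]],
                       params: MinimizerParams,
                       n_buckets: int = 256) -> dict[int, list[ExtendedSegment]]:
    """In-memory bucket router: every extended segment keyed by its bucket.

    ``inputs`` is a sequence of (record stream, color id) pairs; use color
    ``NO_COLOR`` for uncolored construction. All segments of one minimizer
    group land in one bucket.
    """
    buckets: dict[int, list[ExtendedSegment]] = {}
    for records, color in inputs:
        for seg in split_records(records, params, color):
            b = assign_bucket(seg.minimizer, n_buckets)
            buckets.setdefault(b, []).append(seg)
    return buckets


# ---------------------------------------------------------------------------
# On-disk bucket format (versioned): magic, codec id, then a zlib-compressed
# stream of length-prefixed records (text, link flags, minimizer, color).
# ---------------------------------------------------------------------------

BUCKET_MAGIC = b"MTGB"
BUCKET_VERSION = 1
_CODECS = {0: "raw", 1: "zlib"}


class BucketFormatError(IOError):
    pass


def write_bucket_file(path: str | Path, segments: Iterable[ExtendedSegment],
                      codec: str = "zlib") -> None:
    codec_id = {v: k for k, v in _CODECS.items()}[codec]
    parts: list[bytes] = []
    for seg in segments:
        text = seg.text.encode("ascii")
        flags = (1 if seg.left_link else 0) | (2 if seg.right_link else 0)
        parts.append(struct.pack("<IBQq", len(text), flags, seg.minimizer, seg.color))
        parts.append(text)
    payload = b"".join(parts)
    if codec == "zlib":
        payload = zlib.compress(payload, 6)
    with open(path, "wb") as fh:
        fh.write(BUCKET_MAGIC + struct.pack("<BB", BUCKET_VERSION, codec_id))
        fh.write(payload)


def read_bucket_file(path: str | Path) -> list[ExtendedSegment]:
    with open(path, "rb") as fh:
        header = fh.read(6)
        if len(header) != 6 or header[:4] != BUCKET_MAGIC:
            raise BucketFormatError(f"{path}: not a bucket file")
        version, codec_id = header[4], header[5]
        if version != BUCKET_VERSION or codec_id not in _CODECS:
            raise BucketFormatError(f"{path}: unsupported version/codec")
        payload = fh.read()
    if _CODECS[codec_id] == "zlib":
        payload = zlib.decompress(payload)
    out: list[ExtendedSegment] = []
    off = 0
    rec = struct.Struct("<IBQq")
    while off < len(payload):
        if off + rec.size > len(payload):
            raise BucketFormatError(f"{path}: truncated record header")
        length, flags, minimizer, color = rec.unpack_from(payload, off)
        off += rec.size
        if off + length > len(payload):
            raise BucketFormatError(f"{path}: truncated record text")
        text = payload[off:off + length].decode("ascii")
        off += length
        out.append(ExtendedSegment(text, bool(flags & 1), bool(flags & 2),
                                   minimizer, color))
    return out


def split_collection(inputs: Sequence[tuple[str | Path, int]],
                     params: MinimizerParams, n_buckets: int,
                     tmp_dir: str | Path, codec: str = "zlib") -> list[Path]:
    """Split whole files into on-disk buckets (the CLI build front end).

    ``inputs`` pairs each FASTA/FASTQ path with its color id (``NO_COLOR``
    when uncolored). Returns the list of bucket file paths written.
    """
    from .io_cli import read_sequences  # local import to avoid a cycle

    tmp = Path(tmp_dir)
    tmp.mkdir(parents=True, exist_ok=True)
    buckets = split_into_buckets(
        ((read_sequences(p), color) for p, color in inputs), params, n_buckets)
    paths: list[Path] = []
    for b in sorted(buckets):
        path = tmp / f"bucket_{b:05d}.mtb"
        write_bucket_file(path, buckets[b], codec=codec)
        paths.append(path)
    return paths
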