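"""Color-set interning and run-length encodings for the colored graph.

A *color* is the integer id of one input file (0-based, in command-line
order). Every k-mer of a colored graph carries the set of colors it appears
in; identical sets are stored once, named by a dense *subset index* assigned
in first-seen order. Deduplication goes through a 128-bit strong hash of the
set's encoded form; on a hash hit the stored set is deep-compared, so a
collision between distinct sets is an observable hard error rather than a
silent corruption.

Two run-length codecs are defined:

* color sets: deltas of the sorted colors (first delta = first color),
  run-length encoded as (delta, count) pairs of variable-length integers;
* per-unitig annotations: maximal runs of equal subset indices over the
  unitig's k-mers, serialized into the FASTA description line as
  ``C:<idx>:<len>[,<idx>:<len>]*``.

The on-disk color map is chunked (fixed number of sets per chunk), each
chunk independently compressed, behind a small versioned container.
"""

from __future__ import annotations

import hashlib
import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

COLOR_MAP_MAGIC = b"MTGC"
COLOR_MAP_VERSION = 1
DEFAULT_CHUNK_SIZE = 1024


class ColorFormatError(ValueError):
    pass


class ColorHashCollisionError(RuntimeError):
    """Two distinct color sets hashed to the same 128-bit value."""


def normalize_colors(colors: Iterable[int]) -> tuple[int, ...]:
    """Sorted, deduplicated, validated color list."""
    out = tuple(sorted(set(colors)))
    if not out:
        raise ColorFormatError("empty color set")
    if out[0] < 0:
        raise ColorFormatError(f"negative color id in {out}")
    return out


# -- varint + delta-RLE codec for a single color set ------------------------

def _write_varint(v: int, out: bytearray) -> None:
    while True:
        b = v & 0x7F
        v >>= 7
        if v:
            out.append(b | 0x80)
        else:
            out.append(b)
            return


def _read_varint(data: bytes, off: int) -> tuple[int, int]:
    shift = 0
    v = 0
    while True:
        if off >= len(data):
            raise ColorFormatError("truncated varint")
        b = data[off]
        off += 1
        v |= (b & 0x7F) << shift
        if not b & 0x80:
            return v, off
        shift += 7


def encode_color_set(colors: Sequence[int]) -> bytes:
    """Delta + run-length encode a normalized color set to bytes."""
    colors = normalize_colors(colors)
    deltas = [colors[0]] + [b - a for a, b in zip(colors, colors[1:])]
    runs: list[tuple[int, int]] = []
    for d in deltas:
        if runs and runs[-1][0] == d:
            runs[-1] = (d, runs[-1][1] + 1)
        else:
            runs.append((d, 1))
    out = bytearray()
    _write_varint(len(runs), out)
    for d, n in runs:
        _write_varint(d, out)
        _write_varint(n, out)
    return bytes(out)


def decode_color_set(data: bytes) -> tuple[int, ...]:
    """Inverse of :func:`encode_color_set`."""
    n_runs, off = _read_varint(data, 0)
    deltas: list[int] = []
    for _ in range(n_runs):
        d, off = _read_varint(data, off)
        n, off = _read_varint(data, off)
        if n < 1:
            raise ColorFormatError("nonpositive run length")
        deltas.extend([d] * n)
    if off != len(data):
        raise ColorFormatError("trailing bytes after color set")
    if not deltas:
        raise ColorFormatError("empty color set")
    colors = [deltas[0]]
    for d in deltas[1:]:
        if d < 1:
            raise ColorFormatError("non-increasing color delta")
        colors.append(colors[-1] + d)
    return tuple(colors)


def color_set_hash(encoded: bytes) -> int:
    """128-bit strong hash of an encoded color set."""
    return int.from_bytes(hashlib.blake2b(encoded, digest_size=16).digest(), "little")


@dataclass
class ColorIndex:
    """Global interning table from color sets to dense subset indices."""

    by_hash: dict[int, int] = field(default_factory=dict)
    sets: list[tuple[int, ...]] = field(default_factory=list)

    def intern(self, colors: Iterable[int]) -> int:
        """Index of the normalized set, appending it on first sight."""
        c = normalize_colors(colors)
        enc = encode_color_set(c)
        h = color_set_hash(enc)
        idx = self.by_hash.get(h)
        if idx is not None:
            if self.sets[idx] != c:  # deep-compare guard on hash hit
                raise ColorHashCollisionError(
                    f"128-bit hash collision between {self.sets[idx]} and {c}")
            return idx
        idx = len(self.sets)
        self.sets.append(c)
        self.by_hash[h] = idx
        return idx

    def get(self, idx: int) -> tuple[int, ...]:
        return self.sets[idx]

    def __len__(self) -> int:
        return len(self.sets)


def intern_color_set(colors: Iterable[int], index: ColorIndex) -> int:
    """Module-level spelling of :meth:`ColorIndex.intern`."""
    return index.intern(colors)


# -- per-unitig run header ---------------------------------------------------

@dataclass(frozen=True)
class ColorRunHeader:
    """Maximal runs of equal subset indices over one unitig's k-mers."""

    runs: tuple[tuple[int, int], ...]  # (subset index, run length)

    @property
    def n_kmers(self) -> int:
        return sum(n for _, n in self.runs)


def encode_run_header(indices: Sequence[int]) -> ColorRunHeader:
    """RLE of the per-k-mer subset indices of one unitig."""
    runs: list[tuple[int, int]] = []
    for idx in indices:
        if runs and runs[-1][0] == idx:
            runs[-1] = (idx, runs[-1][1] + 1)
        else:
            runs.append((idx, 1))
    return ColorRunHeader(tuple(runs))


def decode_run_header(header: ColorRunHeader, n_kmers: int | None = None) -> list[int]:
    """Per-k-mer subset indices; validates the total against ``n_kmers``."""
    out: list[int] = []
    for idx, n in header.runs:
        if n < 1:
            raise ColorFormatError("nonpositive run length in header")
        out.extend([idx] * n)
    if n_kmers is not None and len(out) != n_kmers:
        raise ColorFormatError(
            f"color runs cover {len(out)} k-mers, expected {n_kmers}")
    return out


def format_run_header(header: ColorRunHeader) -> str:
    """FASTA description form: ``C:<idx>:<len>[,<idx>:<len>]*``."""
    return "C:" + ",".join(f"{idx}:{n}" for idx, n in header.runs)


def parse_run_header(text: str) -> ColorRunHeader:
    if not text.startswith("C:"):
        raise ColorFormatError(f"malformed color header {text!r}")
    runs = []
    for part in text[2:].split(","):
        try:
            idx, n = part.split(":")
            runs.append((int(idx), int(n)))
        except ValueError as e:
            raise ColorFormatError(f"malformed color run {part!r}") from e
    return ColorRunHeader(tuple(runs))


# -- chunked on-disk color map ----------------------------------------------

def write_color_map(index: ColorIndex, path: str | Path,
                    chunk_size: int = DEFAULT_CHUNK_SIZE) -> None:
    """Write the finalized index: chunk directory + compressed chunks."""
    chunks: list[bytes] = []
    for start in range(0, len(index), chunk_size):
        body = bytearray()
        for s in index.sets[start:start + chunk_size]:
            enc = encode_color_set(s)
            _write_varint(len(enc), body)
            body.extend(enc)
        chunks.append(zlib.compress(bytes(body), 6))
    with open(path, "wb") as fh:
        fh.write(COLOR_MAP_MAGIC)
        fh.write(struct.pack("<BIQ", COLOR_MAP_VERSION, chunk_size, len(index)))
        fh.write(struct.pack("<I", len(chunks)))
        for c in chunks:
            fh.write(struct.pack("<I", len(c)))
        for c in chunks:
            fh.write(c)


def read_color_map(path: str | Path) -> ColorIndex:
    with open(path, "rb") as fh:
        if fh.read(4) != COLOR_MAP_MAGIC:
            raise ColorFormatError(f"{path}: not a color map")
        version, chunk_size, n_sets = struct.unpack("<BIQ", fh.read(13))
        if version != COLOR_MAP_VERSION:
            raise ColorFormatError(f"{path}: unsupported version {version}")
        (n_chunks,) = struct.unpack("<I", fh.read(4))
        sizes = [struct.unpack("<I", fh.read(4))[0] for _ in range(n_chunks)]
        index = ColorIndex()
        for size in sizes:
            body = zlib.decompress(fh.read(size))
            off = 0
            while off < len(body):
                length, off = _read_varint(body, off)
                enc = body[off:off + length]
                off += length
                colors = decode_color_set(enc)
                index.by_hash[color_set_hash(enc)] = len(index.sets)
                index.sets.append(colors)
    if len(index.sets) != n_sets:
        raise ColorFormatError(f"{path}: expected {n_sets} sets, read {len(index.sets)}")
    return index
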