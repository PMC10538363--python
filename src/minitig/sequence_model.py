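"""DNA string primitives: canonical forms, occurrence counting, overlap merging.

All sequences are plain Python ``str`` over the alphabet ``{A, C, G, T}``.
Reverse complements are first-class: a k-mer is identified with its reverse
complement throughout (*canonical* k-mers), and a dedicated counting
operation :func:`occ_cn` counts a string together with its reverse
complement, with the palindrome case counted once.

Coordinates are 0-based, half-open everywhere.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterator

ALPHABET = "ACGT"
_ALPHABET_SET = frozenset(ALPHABET)
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class InvalidSequenceError(ValueError):
    """Raised when a sequence contains characters outside {A, C, G, T}."""


class OverlapError(ValueError):
    """Raised when :func:`merge_overlap` is called with a mismatched overlap."""


class Orientation(enum.Enum):
    """Strand of a sequence relative to its stored (or canonical) form."""

    FORWARD = "+"
    REVERSE = "-"

    def flipped(self) -> "Orientation":
        return Orientation.REVERSE if self is Orientation.FORWARD else Orientation.FORWARD


@dataclass(frozen=True)
class CountingParams:
    """Graph-defining parameters: k-mer size, abundance threshold, strand model.

    ``k`` is the k-mer (edge) length, ``a`` the minimum canonical abundance
    for a k-mer to enter the graph, and ``canonical_mode`` selects whether
    k-mers are identified with their reverse complements.
    """

    k: int
    a: int = 1
    canonical_mode: bool = True

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError(f"k must be >= 2, got {self.k}")
        if self.a < 1:
            raise ValueError(f"abundance threshold must be >= 1, got {self.a}")


def validate_dna(s: str) -> str:
    """Return ``s`` unchanged if it is a nonempty string over {A,C,G,T}."""
    if not s:
        raise InvalidSequenceError("empty sequence")
    if not _ALPHABET_SET.issuperset(s):
        bad = sorted(set(s) - _ALPHABET_SET)
        raise InvalidSequenceError(f"invalid characters {bad} in sequence")
    return s


def reverse_complement(s: str) -> str:
    """Reverse complement (A<->T, C<->G, reversed). An involution."""
    return s.translate(_COMPLEMENT)[::-1]


def canonical(s: str) -> tuple[str, Orientation]:
    """Canonical representative of a strand pair and the producing orientation.

    The representative is the lexicographic minimum of ``s`` and its reverse
    complement; palindromes report ``FORWARD``.
    """
    rc = reverse_complement(s)
    if rc < s:
        return rc, Orientation.REVERSE
    return s, Orientation.FORWARD


def canonical_str(s: str) -> str:
    """Canonical representative only (fast path for table keys)."""
    rc = s.translate(_COMPLEMENT)[::-1]
    return rc if rc < s else s


def merge_overlap(x: str, y: str, t: int) -> str:
    """Merge ``x`` and ``y`` overlapping on exactly ``t`` characters.

    Requires ``suf_t(x) == pre_t(y)``; the result is ``x`` followed by ``y``
    minus its first ``t`` characters, of length ``|x| + |y| - t``.
    """
    if t < 0 or t > len(x) or t > len(y):
        raise OverlapError(f"overlap length {t} out of range for |x|={len(x)}, |y|={len(y)}")
    if x[len(x) - t:] != y[:t]:
        raise OverlapError(f"suffix/prefix mismatch on overlap of length {t}")
    return x + y[t:]


def occ(x: str, R) -> int:
    """Occurrences of ``x`` in the strings of ``R``, overlapping ones included."""
    n = 0
    for r in R:
        start = r.find(x)
        while start != -1:
            n += 1
            start = r.find(x, start + 1)
    return n


def occ_cn(x: str, R) -> int:
    """Canonical occurrence count of ``x`` in the multiset ``R``.

    Counts occurrences of ``x`` plus occurrences of its reverse complement;
    a palindrome (``x == rc(x)``) is counted once per occurrence, not twice.
    """
    rc = reverse_complement(x)
    if x == rc:
        return occ(x, R)
    return occ(x, R) + occ(rc, R)


def app(x: str, R) -> int:
    return 1 if occ(x, R) >= 1 else 0


def app_cn(x: str, R) -> int:
    return 1 if occ_cn(x, R) >= 1 else 0


def kmers_of(s: str, k: int) -> Iterator[str]:
    """All k-mers of ``s``, left to right (empty when ``len(s) < k``)."""
    for i in range(len(s) - k + 1):
        yield s[i:i + k]


def acgt_runs(s: str, min_len: int = 1) -> list[str]:
    """Split ``s`` at non-ACGT characters into maximal ACGT runs.

    Runs shorter than ``min_len`` are dropped. This is how ambiguous bases
    (N and other IUPAC codes) are handled upstream of graph construction.
    """
    runs: list[str] = []
    start = None
    s = s.upper()
    for i, c in enumerate(s):
        if c in _ALPHABET_SET:
            if start is None:
                start = i
        else:
            if start is not None and i - start >= min_len:
                runs.append(s[start:i])
            start = None
    if start is not None and len(s) - start >= min_len:
        runs.append(s[start:])
    return runs


def normalize_linear(s: str) -> str:
    """Strand-normalized form of a linear unitig: min(s, rc(s))."""
    return canonical_str(s)


def spell_cycle(core: str, k: int) -> str:
    """Linear spelling of a circular unitig: the core plus a k-1 wrap.

    The wrap repeats the core when the cycle has fewer than k-1 characters
    (e.g. a homopolymer self-loop), so the spelling contains every k-mer of
    the cycle exactly once.
    """
    reps = (k - 2) // len(core) + 1
    return core + (core * reps)[:k - 1]


def normalize_cycle(core: str) -> str:
    """Rotation- and strand-normalized core of a circular unitig.

    ``core`` is the cyclic sequence (length = number of k-mers of the cycle);
    the result is the lexicographically least rotation over both strands, so
    equivalent cycles compare equal.
    """
    best = None
    for cand in (core, reverse_complement(core)):
        doubled = cand + cand
        for i in range(len(cand)):
            rot = doubled[i:i + len(cand)]
            if best is None or rot < best:
                best = rot
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# 128-bit Rabin-Karp k-mer hashing for the long-k (k > 64) representation.
# ---------------------------------------------------------------------------

RK128_MASK = (1 << 128) - 1
#: Per-base prime codes; each base maps to a different prime.
RK128_BASE_CODES = {"A": 2, "C": 3, "G": 5, "T": 7}
#: Odd multiplier for the rolling polynomial (fixed constant of the format).
RK128_MULTIPLIER = 0x9E3779B97F4A7C15F39CC0605CEDC835


class Rk128:
    """Rolling 128-bit polynomial hash over k-length windows.

    ``h(s) = sum_i code(s_i) * B^(k-1-i) mod 2^128`` with per-base prime
    codes. Nonbijective for k > 64: distinct k-mers may collide, which a
    caller can detect (not correct) by comparing extension contexts.
    """

    def __init__(self, k: int):
        self.k = k
        self._top = pow(RK128_MULTIPLIER, k - 1, 1 << 128)

    def hash(self, s: str) -> int:
        if len(s) != self.k:
            raise ValueError(f"expected a {self.k}-mer, got length {len(s)}")
        h = 0
        for c in s:
            h = (h * RK128_MULTIPLIER + RK128_BASE_CODES[c]) & RK128_MASK
        return h

    def roll(self, h: int, out_char: str, in_char: str) -> int:
        """Hash of the window shifted by one character, in O(1)."""
        h = (h - RK128_BASE_CODES[out_char] * self._top) & RK128_MASK
        return (h * RK128_MULTIPLIER + RK128_BASE_CODES[in_char]) & RK128_MASK


def rk128_hash(s: str) -> int:
    """Convenience one-shot 128-bit Rabin-Karp hash of ``s`` (k = len(s))."""
    return Rk128(len(s)).hash(s)
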