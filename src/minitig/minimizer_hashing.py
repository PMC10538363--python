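"""Rolling m-mer hashing and per-(k-1)-mer minimizers.

The minimizer of a window is the minimum *hash value* over its constituent
m-mers; following the construction algorithm, the minimizer is a value only
and carries no position. Two hash families are provided:

``mix64``
    The production hash: the m-mer is 2-bit encoded in a rolling manner and
    the code is passed through a 64-bit finalizer (splitmix64-style). This
    adopts the contract of a fast rolling hash with well-mixed output, not
    any particular tool's bit-level algorithm.

``rank``
    A toy hash equal to the base-4 rank of the m-mer (A=0, C=1, G=2, T=3),
    useful for worked examples whose minima can be read off by hand.

In canonical mode every m-mer is hashed through its canonical representative
so the hash — and hence every window minimizer — is invariant under reverse
complement of the sequence.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

from .sequence_model import canonical_str

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_MASK64 = (1 << 64) - 1


def _mix64(v: int) -> int:
    """splitmix64 finalizer: a well-mixed 64-bit permutation."""
    v = (v + 0x9E3779B97F4A7C15) & _MASK64
    v = ((v ^ (v >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    v = ((v ^ (v >> 27)) * 0x94D049BB133111EB) & _MASK64
    return v ^ (v >> 31)


def _rank(v: int) -> int:
    return v


HASH_FINALIZERS = {"mix64": _mix64, "rank": _rank}


def choose_m(k: int, m: int | None = None) -> int:
    """Default minimizer length for a given k (user-supplied ``m`` overrides).

    The rule is ``m = min(12, k - 2)`` with a floor of 4 once ``k >= 6``
    (clamped to at least 1 below that). Any valid m only affects how work is
    distributed across buckets, never the unitig set.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if m is not None:
        if not 1 <= m <= k - 1:
            raise ValueError(f"m must satisfy 1 <= m <= k-1, got m={m}, k={k}")
        return m
    if k < 6:
        return max(1, min(12, k - 2))
    return max(4, min(12, k - 2))


@dataclass(frozen=True)
class MinimizerParams:
    """Minimizer configuration: window geometry and the pluggable m-mer hash."""

    k: int
    m: int
    hash_name: str = "mix64"
    canonical: bool = True

    def __post_init__(self) -> None:
        if not 1 <= self.m <= self.k - 1:
            raise ValueError(f"require 1 <= m <= k-1, got m={self.m}, k={self.k}")
        if self.hash_name not in HASH_FINALIZERS:
            raise ValueError(f"unknown hash {self.hash_name!r}")

    @property
    def window(self) -> int:
        """Number of m-mers per (k-1)-mer window."""
        return self.k - self.m


def hash_mmer(x: str, hash_name: str = "mix64", canonical: bool = True) -> int:
    """Hash a single m-mer; in canonical mode, x and rc(x) hash equal."""
    if canonical:
        x = canonical_str(x)
    v = 0
    for c in x:
        v = (v << 2) | _CODE[c]
    return HASH_FINALIZERS[hash_name](v)


def canonical_hash(x: str, hash_name: str = "mix64") -> int:
    """Canonical m-mer hash: ``hash(canonical(x))``, equal for x and rc(x)."""
    return hash_mmer(x, hash_name, canonical=True)


def rolling_hashes(s: str, m: int, hash_name: str = "mix64",
                   canonical: bool = True) -> list[int]:
    """One hash per m-mer of ``s``, left to right (empty when ``len(s) < m``).

    The 2-bit code of each window is maintained incrementally (and, in
    canonical mode, the code of the reverse complement alongside it); the
    output is identical to hashing each m-mer independently.
    """
    n = len(s)
    if n < m:
        return []
    finalize = HASH_FINALIZERS[hash_name]
    mask = (1 << (2 * m)) - 1
    shift = 2 * (m - 1)
    fwd = 0
    rev = 0
    out: list[int] = []
    for i, c in enumerate(s):
        code = _CODE[c]
        fwd = ((fwd << 2) | code) & mask
        rev = (rev >> 2) | ((3 - code) << shift)
        if i >= m - 1:
            if canonical:
                # numeric min of the 2-bit codes == lexicographic min of the
                # strings because A<C<G<T maps to 0<1<2<3
                out.append(finalize(min(fwd, rev)))
            else:
                out.append(finalize(fwd))
    return out


def window_minimizers(s: str, params: MinimizerParams) -> list[int]:
    """Minimizer of every (k-1)-mer of ``s`` in a single pass.

    Each (k-1)-mer contains ``k - m`` consecutive m-mers; its minimizer is
    the minimum hash over them, computed with a monotonic deque so the whole
    sequence is processed in O(|s|). Returns ``len(s) - (k-1) + 1`` values
    (empty when ``len(s) < k - 1``).
    """
    k, m = params.k, params.m
    if len(s) < k - 1:
        return []
    hashes = rolling_hashes(s, m, params.hash_name, params.canonical)
    w = params.window
    assert w >= 1
    mins: list[int] = []
    dq: deque[int] = deque()  # indices into hashes, values nondecreasing
    for i, h in enumerate(hashes):
        while dq and hashes[dq[-1]] > h:
            dq.pop()
        dq.append(i)
        if dq[0] <= i - w:
            dq.popleft()
        if i >= w - 1:
            mins.append(hashes[dq[0]])
    return mins


def kmer_minimizers(s: str, params: MinimizerParams) -> list[int]:
    """Minimizer of every k-mer of ``s`` (minimum of its two (k-1)-windows)."""
    wins = window_minimizers(s, params)
    return [min(wins[i], wins[i + 1]) for i in range(len(wins) - 1)]
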