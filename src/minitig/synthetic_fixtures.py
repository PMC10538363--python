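"""Deterministic generators for every input class used in tests.

All generators are pure functions of their seed and parameters — no
external data is ever downloaded. They emulate the input classes a graph
builder meets in practice: assembled genomes, shotgun reads sampled from
both strands with substitution errors, multi-sample collections with shared
and private sequence for the colored graph, and adversarial shapes
(circular chromosomes, tandem repeats, palindromes, too-short reads).
"""

from __future__ import annotations

import random
from typing import Sequence

from .sequence_model import ALPHABET, reverse_complement

_OTHER = {c: ALPHABET.replace(c, "") for c in ALPHABET}


def random_genome(length: int, seed: int) -> str:
    """Uniform i.i.d. bases; reproducible; length 0 gives the empty string."""
    rng = random.Random(seed)
    return "".join(rng.choices(ALPHABET, k=length))


def sample_reads(genome: str, read_len: int, coverage: float,
                 rc_prob: float = 0.5, error_rate: float = 0.0,
                 seed: int = 0) -> list[tuple[str, str]]:
    """Reads from both strands with substitution errors, at given coverage.

    A deterministic tiling pass with half-length overlaps guarantees every
    genome window of length <= read_len/2 + 1 is covered, so with
    ``error_rate`` 0 the reads' canonical k-mer set equals the genome's for
    any such k; uniformly positioned reads then fill up to the requested
    coverage. Each read is reverse-complemented with probability
    ``rc_prob``; errors are substitutions only.
    """
    rng = random.Random(seed)
    read_len = min(read_len, len(genome))
    if read_len == 0:
        return []

    starts = list(range(0, max(1, len(genome) - read_len + 1),
                        max(1, read_len // 2)))
    if starts[-1] != len(genome) - read_len:
        starts.append(len(genome) - read_len)
    n_total = max(len(starts), round(coverage * len(genome) / read_len))
    while len(starts) < n_total:
        starts.append(rng.randint(0, len(genome) - read_len))

    out: list[tuple[str, str]] = []
    for i, start in enumerate(starts):
        seq = genome[start:start + read_len]
        if error_rate > 0:
            seq = "".join(
                rng.choice(_OTHER[c]) if rng.random() < error_rate else c
                for c in seq)
        if rng.random() < rc_prob:
            seq = reverse_complement(seq)
        out.append((f"read{i}", seq))
    return out


def tile_reads(genome: str, read_len: int, overlap: int,
               rc_prob: float = 0.5, seed: int = 0) -> list[tuple[str, str]]:
    """Error-free reads tiling the genome end to end with a fixed overlap.

    With ``overlap >= k - 1`` the reads' canonical k-mer multiset covers the
    genome's exactly (every k-mer occurs in some read), which makes the
    read-based and genome-based graphs comparable in tests.
    """
    rng = random.Random(seed)
    step = max(1, read_len - overlap)
    out = []
    i = 0
    pos = 0
    while True:
        seq = genome[pos:pos + read_len]
        if len(seq) < read_len:
            seq = genome[max(0, len(genome) - read_len):]
        if seq:
            if rng.random() < rc_prob:
                seq = reverse_complement(seq)
            out.append((f"tile{i}", seq))
        if pos + read_len >= len(genome):
            break
        pos += step
        i += 1
    return out


def color_collection(n_colors: int, shared_fraction: float, seed: int,
                     total_len: int = 2000
                     ) -> tuple[list[list[tuple[str, str]]], str, list[str]]:
    """A colored-graph input: one record list per color.

    Every color carries a common backbone genome (``shared_fraction`` of
    ``total_len``) plus a private segment of its own, so the expected color
    structure is known by construction: backbone k-mers belong to all
    colors, private k-mers to exactly one (up to chance repeats). Returns
    (per-color records, backbone, private segments).
    """
    rng = random.Random(seed)
    backbone_len = int(total_len * shared_fraction)
    private_len = max(0, total_len - backbone_len)
    backbone = random_genome(backbone_len, rng.randrange(2**31))
    files: list[list[tuple[str, str]]] = []
    privates: list[str] = []
    for c in range(n_colors):
        private = random_genome(private_len, rng.randrange(2**31))
        privates.append(private)
        files.append([(f"c{c}_backbone", backbone), (f"c{c}_private", private)])
    return files, backbone, privates


def adversarial_fixtures(seed: int, k: int) -> dict[str, list[tuple[str, str]]]:
    """Named stress inputs exercising the pipeline's edge cases.

    - ``circular``: a circular chromosome given with a k-1 wrap, whose
      graph is a single cyclic unitig;
    - ``tandem_repeat``: an exact repeat creating branching (k-1)-mers;
    - ``minimizer_boundary``: a low-complexity/random mosaic with rapid
      minimizer turnover, stressing segment boundaries;
    - ``palindromes``: sequence concatenated with its reverse complement
      (palindromic junctions; with even k also palindromic k-mers);
    - ``short_reads``: reads shorter than k that must be skipped;
    - ``rc_pair``: a sequence and its reverse complement as two records.
    """
    rng = random.Random(seed)
    core = random_genome(40 * k, rng.randrange(2**31))
    circular = core + core[:k - 1]
    unit = random_genome(3 * k, rng.randrange(2**31))
    spacer = random_genome(2 * k, rng.randrange(2**31))
    tandem = spacer + unit * 3 + spacer[::-1].translate(str.maketrans("ACGT", "TGCA"))
    mosaic_parts = []
    for _ in range(12):
        mosaic_parts.append(rng.choice(ALPHABET) * rng.randint(2, k))
        mosaic_parts.append(random_genome(rng.randint(k, 2 * k),
                                          rng.randrange(2**31)))
    mosaic = "".join(mosaic_parts)
    pal_base = random_genome(10 * k, rng.randrange(2**31))
    palin = pal_base + reverse_complement(pal_base)
    genome = random_genome(20 * k, rng.randrange(2**31))
    return {
        "circular": [("circ", circular)],
        "tandem_repeat": [("tandem", tandem)],
        "minimizer_boundary": [("mosaic", mosaic)],
        "palindromes": [("palin", palin)],
        "short_reads": [("long", genome)] + [
            (f"short{i}", random_genome(rng.randint(1, k - 1),
                                        rng.randrange(2**31)))
            for i in range(3)],
        "rc_pair": [("fwd", genome), ("rev", reverse_complement(genome))],
    }
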