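"""Brute-force ground truth for de Bruijn graph construction and querying.

Everything here recomputes results directly from the definitions, with no
bucketing, no linking characters and no shared extension code with the
production pipeline, so that equality tests between the two are meaningful.
The oracle may be asymptotically slower; clarity wins over speed.

Two independent unitig constructions are provided — edge-centric (a global
greedy over the filtered canonical k-mer set) and node-centric (an explicit
adjacency-graph path decomposition) — plus machine-checkable assertions for
the string-centric conditions defining canonical maximal unitigs and for
the structural properties of the read-splitting step.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping, Sequence

from .minimizer_hashing import MinimizerParams, window_minimizers
from .sequence_model import (
    ALPHABET,
    CountingParams,
    canonical_str,
    normalize_cycle,
    occ_cn,
    reverse_complement,
    spell_cycle,
)

Unitig = tuple[str, bool]  # (spelling, is_cycle); cycles spelled with k-1 wrap


def enumerate_kmers(R: Iterable[str], params: CountingParams) -> dict[str, int]:
    """Exact canonical k-mer abundances of ``R``, filtered at threshold a.

    Scanning every position and folding to the canonical form counts each
    occurrence of a k-mer or of its reverse complement once, which is the
    canonical occurrence count (palindromes included, without doubling).
    """
    k = params.k
    counts: Counter[str] = Counter()
    fold = canonical_str if params.canonical_mode else (lambda s: s)
    for r in R:
        for i in range(len(r) - k + 1):
            counts[fold(r[i:i + k])] += 1
    return {q: n for q, n in counts.items() if n >= params.a}


def _extension(s_next: str, K, fold, k: int, rightward: bool) -> str | None:
    """Unique both-ways extension across the junction (k-1)-mer, or None."""
    if rightward:
        fw = [s_next + c for c in ALPHABET if fold(s_next + c) in K]
        if len(fw) != 1:
            return None
        bw = [c + s_next for c in ALPHABET if fold(c + s_next) in K]
    else:
        fw = [c + s_next for c in ALPHABET if fold(c + s_next) in K]
        if len(fw) != 1:
            return None
        bw = [s_next + c for c in ALPHABET if fold(s_next + c) in K]
    if len(bw) != 1:
        return None
    return fw[0]


def maximal_unitigs_bruteforce(R: Iterable[str],
                               params: CountingParams) -> set[Unitig]:
    """Canonical maximal unitigs computed greedily over the global k-mer set.

    Every filtered canonical k-mer seeds a bidirectional extension under the
    both-ways-unique rule; a candidate already consumed by the growing
    string either closes a cycle (when it is the oriented starting k-mer)
    or is a reverse-complement fold-back where the unitig ends. Output is
    normalized: linear unitigs by strand, cycles by rotation and strand.
    """
    k = params.k
    fold = canonical_str if params.canonical_mode else (lambda s: s)
    K = enumerate_kmers(R, params)
    used: set[str] = set()
    out: set[Unitig] = set()
    for seed in sorted(K):
        if seed in used:
            continue
        used.add(seed)
        left_parts: list[str] = []  # reversed prepended characters
        right_parts: list[str] = []
        first_kmer = last_kmer = seed
        consumed = {seed}
        is_cycle = False
        # rightward then leftward
        for rightward in (True, False):
            while True:
                cur = last_kmer if rightward else first_kmer
                s_next = cur[1:] if rightward else cur[:k - 1]
                y = _extension(s_next, K, fold, k, rightward)
                if y is None:
                    break
                fy = fold(y)
                if fy in consumed:
                    if y == (first_kmer if rightward else last_kmer):
                        is_cycle = True
                    break
                if fy in used:
                    break
                used.add(fy)
                consumed.add(fy)
                if rightward:
                    right_parts.append(y[-1])
                    last_kmer = y
                else:
                    left_parts.append(y[0])
                    first_kmer = y
            if is_cycle:
                break
        text = "".join(reversed(left_parts)) + seed + "".join(right_parts)
        if is_cycle:
            core = text[:len(text) - (k - 1)]
            core = (normalize_cycle(core) if params.canonical_mode
                    else _rot_min(core))
            out.add((spell_cycle(core, k), True))
        else:
            out.add((fold(text) if params.canonical_mode else text, False))
    return out


def _rot_min(core: str) -> str:
    doubled = core + core
    return min(doubled[i:i + len(core)] for i in range(len(core)))


def node_centric_unitigs_bruteforce(R: Iterable[str],
                                    params: CountingParams) -> set[Unitig]:
    """Unitigs of the node-centric graph: k-mers as nodes, (k-1)-overlaps as
    edges, with the standard extra condition that consecutive nodes must be
    each other's unique successor/predecessor.

    Built as an explicit link map followed by a path/cycle decomposition
    (no greedy growth), and used to certify the node-/edge-centric
    equivalence on concrete inputs.
    """
    k = params.k
    canonical = params.canonical_mode
    fold = canonical_str if canonical else (lambda s: s)
    K = set(enumerate_kmers(R, params))

    def oriented_forms(q: str):
        if not canonical:
            return (q,)
        rc = reverse_complement(q)
        return (q,) if rc == q else (q, rc)

    def succ(q: str) -> str | None:
        outs = [q[1:] + c for c in ALPHABET if fold(q[1:] + c) in K]
        if len(outs) != 1:
            return None
        r = outs[0]
        ins = [c + r[:k - 1] for c in ALPHABET if fold(c + r[:k - 1]) in K]
        if len(ins) != 1:
            return None
        return r

    # linked[q] = r means edge q->r is traversable inside a unitig
    linked: dict[str, str] = {}
    for x in K:
        for q in oriented_forms(x):
            r = succ(q)
            if r is not None:
                linked[q] = r
    has_pred = {r for r in linked.values()}

    visited: set[str] = set()
    out: set[Unitig] = set()

    def walk(start: str) -> tuple[list[str], bool]:
        path = [start]
        seen = {fold(start)}
        cur = start
        while True:
            nxt = linked.get(cur)
            if nxt is None:
                return path, False
            if fold(nxt) in seen:
                return path, nxt == start  # cycle iff it returns to the head
            path.append(nxt)
            seen.add(fold(nxt))
            cur = nxt

    # maximal paths start at nodes with no traversable predecessor
    for x in sorted(K):
        for q in oriented_forms(x):
            if q in has_pred or fold(q) in visited:
                continue
            path, _ = walk(q)
            visited.update(fold(p) for p in path)
            out.add((_spell(path, k, canonical, cycle=False), False))
    # remaining components: cycles, or fold-back paths with no free head;
    # walk forward from an arbitrary node, then complete backward
    pred = {r: q for q, r in linked.items()}
    for x in sorted(K):
        if x in visited:
            continue
        start = oriented_forms(x)[0]
        path, is_cycle = walk(start)
        if not is_cycle:
            seen = {fold(p) for p in path}
            cur = start
            while True:
                prv = pred.get(cur)
                if prv is None or fold(prv) in seen:
                    break
                path.insert(0, prv)
                seen.add(fold(prv))
                cur = prv
        visited.update(fold(p) for p in path)
        out.add((_spell(path, k, canonical, cycle=is_cycle), is_cycle))
    return out


def _spell(path: Sequence[str], k: int, canonical: bool, cycle: bool) -> str:
    text = path[0] + "".join(q[-1] for q in path[1:])
    if cycle:
        core = text[:len(text) - (k - 1)]
        core = normalize_cycle(core) if canonical else _rot_min(core)
        return spell_cycle(core, k)
    return canonical_str(text) if canonical else text


# ---------------------------------------------------------------------------
# Machine-checkable conditions for canonical maximal unitig sets.
# ---------------------------------------------------------------------------

def check_canonical_maximal_unitigs(U: Iterable[Unitig], R: Sequence[str],
                                    params: CountingParams) -> list[str]:
    """Assert the string-centric conditions of the canonical maximal unitig
    definition on an output set; returns a list of violations (empty = ok).

    Checked literally: minimum length, no reverse-complement duplicates
    among distinct strings, exact canonical k-mer content at the abundance
    threshold, branching (k-1)-mers confined to string ends, and
    unextendability of every end. An end whose unique continuation k-mer
    already belongs to the same unitig (a cycle wrap or a reverse-complement
    fold-back) is unextendable: a path cannot reuse an edge.
    """
    k, a = params.k, params.a
    problems: list[str] = []
    U = list(U)
    texts = [t for t, _ in U]

    for t, _ in U:
        if len(t) < k:
            problems.append(f"unitig shorter than k: {t}")
    for i, (t, _) in enumerate(U):
        for t2, _ in U[i + 1:]:
            if t == reverse_complement(t2):
                problems.append(f"reverse-complement duplicate pair: {t}")

    expected = set(enumerate_kmers(R, params))
    got: Counter[str] = Counter()
    for t, _ in U:
        for i in range(len(t) - k + 1):
            got[canonical_str(t[i:i + k])] += 1
    if set(got) != expected:
        missing = list(expected - set(got))[:3]
        extra = list(set(got) - expected)[:3]
        problems.append(f"k-mer content differs (missing {missing}, extra {extra})")

    # branching (k-1)-mers appear only as prefixes/suffixes
    km1_occ: Counter[str] = Counter()
    internal: set[str] = set()
    for t, _ in U:
        n = len(t) - (k - 1) + 1
        for i in range(n):
            q = canonical_str(t[i:i + k - 1])
            km1_occ[q] += 1
            if 0 < i < n - 1:
                internal.add(q)
    for q, c in km1_occ.items():
        if c > 1 and q in internal:
            problems.append(f"branching (k-1)-mer {q} occurs internally")

    # maximality: no end may admit a fresh both-ways-unique extension
    fold = canonical_str
    for t, is_cycle in U:
        if is_cycle:
            continue
        own = {fold(t[i:i + k]) for i in range(len(t) - k + 1)}
        for rightward in (True, False):
            s = t[-(k - 1):] if rightward else t[:k - 1]
            y = _extension(s, expected, fold, k, rightward)
            if y is not None and fold(y) not in own:
                problems.append(f"unitig end {s} extendable to {y}: not maximal")
    return problems


# ---------------------------------------------------------------------------
# Structural checks for the read-splitting step.
# ---------------------------------------------------------------------------

def check_split_groups(groups: Mapping[int, Sequence[str]], R: Sequence[str],
                       params: MinimizerParams) -> list[str]:
    """Brute-force the three grouping properties of minimizer splitting.

    ``groups`` maps each minimizer value to the extended-segment texts of
    its group. For every k-mer string of the input: (a) it appears in at
    most two groups, in exactly two iff its prefix- and suffix-(k-1)-mer
    minimizers differ; (b) its occurrence count inside any group containing
    it equals its count in the reads; (c) if its own minimizer is h, every
    k-mer overlapping it by k-1 appears in group h.
    """
    k = params.k
    problems: list[str] = []
    kmer_strings = {r[i:i + k] for r in R for i in range(len(r) - k + 1)}
    canon_seen: set[str] = set()

    def cn_texts(x: str, texts: Sequence[str]) -> int:
        return occ_cn(x, texts) if params.canonical else _occ(x, texts)

    group_ids = sorted(groups)
    for x in sorted(kmer_strings):
        cx = canonical_str(x) if params.canonical else x
        if cx in canon_seen:
            continue
        canon_seen.add(cx)
        h_pre = window_minimizers(x[:k - 1], params)[0]
        h_suf = window_minimizers(x[1:], params)[0]
        containing = [h for h in group_ids if cn_texts(x, groups[h]) > 0]
        if len(containing) > 2:
            problems.append(f"{x} appears in {len(containing)} groups")
        if (len(containing) == 2) != (h_pre != h_suf):
            problems.append(
                f"{x}: in groups {containing} but window minimizers "
                f"{'differ' if h_pre != h_suf else 'coincide'}")
        n_reads = cn_texts(x, R)
        for h in containing:
            n_grp = cn_texts(x, groups[h])
            if n_grp != n_reads:
                problems.append(
                    f"{x}: occ {n_grp} in group {h} != {n_reads} in reads")
        # (c): neighbors of a link-free k-mer are present in its group;
        # x is link-free only when both its windows share one minimizer
        if h_pre != h_suf:
            continue
        h = h_pre
        forms = (x, reverse_complement(x)) if params.canonical else (x,)
        for q in forms:
            for c in ALPHABET:
                for y in (q[1:] + c, c + q[:k - 1]):
                    if (y in kmer_strings
                            or (params.canonical
                                and reverse_complement(y) in kmer_strings)):
                        if cn_texts(y, groups.get(h, ())) == 0:
                            problems.append(
                                f"neighbor {y} of {x} missing from group {h}")
    return problems


def _occ(x: str, texts: Sequence[str]) -> int:
    n = 0
    for t in texts:
        start = t.find(x)
        while start != -1:
            n += 1
            start = t.find(x, start + 1)
    return n


# ---------------------------------------------------------------------------
# Query oracle.
# ---------------------------------------------------------------------------

def query_oracle(graph_sequences: Iterable[str],
                 queries: Sequence[tuple[str, str]], k: int,
                 per_color_sequences: Mapping[int, Sequence[str]] | None = None,
                 canonical: bool = True) -> list[dict]:
    """Naive per-position membership scan used as query ground truth.

    Returns one dict per query: id, total k-mers, matched count, and (when
    ``per_color_sequences`` is given) positive per-color matched counts
    computed from per-file canonical k-mer sets.
    """
    fold = canonical_str if canonical else (lambda s: s)
    graph = {fold(s[i:i + k]) for s in graph_sequences
             for i in range(len(s) - k + 1)}
    color_sets = None
    if per_color_sequences is not None:
        color_sets = {
            c: {fold(s[i:i + k]) for s in seqs for i in range(len(s) - k + 1)}
            for c, seqs in per_color_sequences.items()
        }
    out = []
    for qid, seq in queries:
        total = max(0, len(seq) - k + 1)
        matched = 0
        per_color: Counter[int] = Counter()
        for i in range(total):
            km = fold(seq[i:i + k])
            if km in graph:
                matched += 1
                if color_sets is not None:
                    for c, ks in color_sets.items():
                        if km in ks:
                            per_color[c] += 1
        res = {"query_id": qid, "total_kmers": total, "matched": matched}
        if color_sets is not None:
            res["per_color"] = dict(per_color)
        out.append(res)
    return out
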