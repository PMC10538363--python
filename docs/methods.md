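# Methods

This note records the model, the parameter choices, the numerical and
design decisions behind `minitig`, and what the synthetic test inputs do
and do not establish about real data.

## Strings, strands, and the output contract

All sequences live over {A, C, G, T}; non-ACGT characters are handled
upstream by splitting inputs into maximal ACGT runs and dropping runs
shorter than k. Coordinates are 0-based half-open throughout.

A k-mer is identified with its reverse complement; the canonical
representative is the lexicographic minimum of the pair (a pure
convention — any deterministic choice works). The canonical occurrence
count occ_cn(x, R) adds the counts of x and of its reverse complement,
counting palindromes (possible only for even k) once.

The output of a build is the set of canonical maximal unitigs of the input
at parameters (k, a): strings of length ≥ k whose canonical k-mer content
is exactly the k-mers with occ_cn ≥ a, in which branching (k−1)-mers occur
only as prefixes or suffixes, no two distinct strings are reverse
complements, and no end can be extended. Circular components are emitted
once, as the lexicographically least rotation over both strands followed
by a k−1 wrap (repeated when the cycle core is shorter than k−1, e.g. a
homopolymer self-loop). Linear unitigs are emitted on their canonical
strand and sorted, so rebuilt outputs are byte-identical.

### Palindromic junctions

For any k, a (k−1)-mer can equal its own reverse complement. At such a
junction the unique continuation of a unitig end can be the reverse
complement of the end k-mer itself (a fold-back). Extending there would
create a string containing a k-mer on both strands and, pushed to the
limit, a string equal to its own reverse complement, which the output
contract forbids. Reading unitigs as paths in the bidirected graph — where
a path may not traverse the same edge twice — the fold-back continuation
is not a legal extension, so both the pipeline and the oracle stop there,
and the maximality checker treats an end whose unique candidate k-mer
already belongs to the same unitig (fold-backs and cycle wraps alike) as
unextendable. Palindromic *k-mers* (even k only) are counted per the
occ_cn definition but are not exercised by default test parameters, which
use odd k; behavior of endpoint pairing at even-k palindromic boundary
k-mers is a known limitation.

## Minimizers and bucketing

The minimizer of a (k−1)-mer is the minimum hash over its k−m constituent
m-mers — a value, not a position. The production m-mer hash 2-bit-encodes
the m-mer in a rolling manner and applies a 64-bit finalizer
(splitmix64); this adopts the contract of the fast rolling hashes used in
this field (uniform output, O(1) per position) without reproducing any
specific tool bit for bit. A deterministic base-4 "rank" hash exists for
worked examples. In canonical mode every m-mer is hashed via its canonical
form, making window minimizers invariant under reverse complement — the
property that makes a read and its reverse complement split into mirrored
segments, which the correctness of grouping under strand folding rests on.

The default minimizer length is m = min(12, k−2), floored at 4 once
k ≥ 6. The choice only shapes bucket balance: the unitig set is provably
and testably independent of m, of the hash function, and of the bucket
count (an end-to-end property test swaps all three).

Groups (one per minimizer value) are packed into n_buckets = 256 buckets
by default (CLI-overridable, power of two) using the low bits of the
minimizer. A bucket is purely a storage unit; counting and extension are
always per group, because a k-mer's neighborhood is only guaranteed
complete within its own group.

## Why in-bucket decisions are globally correct

Every k-mer whose two (k−1)-mer windows share minimizer h occurs only
inside single segments of group h and is link-free there; if the windows'
minimizers differ (h₁ ≠ h₂), every occurrence straddles a segment
boundary, and the k-mer appears in exactly the two groups h₁ and h₂,
carrying a linking character on the boundary-facing side in each. Both
facts are functions of the k-mer string alone, so they hold uniformly over
all occurrences. Consequently: group abundances equal global canonical
abundances (so the abundance filter is exact per group); every neighbor
query made during extension touches a (k−1)-mer window with the group's
own minimizer, whose full global neighborhood is present in the group; and
each link-flagged k-mer is terminal in exactly one unitig per group with
exactly one blocked side, producing exactly one endpoint record per group,
i.e. exactly two per canonical boundary k-mer overall. The merge step
asserts this invariant and fails loudly rather than producing a wrong
graph.

Side-aware link flags (left/right in canonical orientation) are a
sharpening of a coarse "contains a linking character" flag: they let a
unitig extend *away* from the blocked side of a terminal k-mer, which is
what guarantees the one-record-per-group accounting above.

## Randomized merging

Paired endpoint records chain intermediate unitigs; chains are paths in a
degree-≤ 2 glue graph whose vertices are intermediate-unitig ids. Each
round, every pending chain picks one unsealed end uniformly at random, is
filed under that end's terminal id into one of 64 merge buckets (hash of
the id), and leaves a placeholder for its other unsealed end. Two chains
filed under the same id concatenate (orientations reconciled; a chain
whose two terminal ids coincide closes into a cycle); a filed end with
neither partner nor foreign placeholder provably has no partner and is
sealed; chains with both ends sealed are final. A 512-round cap guards the
(probability-zero-in-practice) nontermination path with a diagnostic.

Two chains that must merge meet when both pick the shared end: probability
1/4 in the worst case of four unsealed ends, hence the expected-four-tries
analysis, which models every try as an independent 1/4 event. The
implemented mechanism is faster than that model in later rounds — an outer
end that seals forces its chain to pick the shared end deterministically —
so the measured quantities are split: the single-round join fraction is
measured on the real `merge_round` (sealing cannot act within one round),
while the expected-tries figure simulates the analysis model explicitly.
Both are reported by `scripts/acceptance.py` at n = 100,000
(Monte-Carlo standard error ≈ 0.0014 on the fraction, ≈ 0.011 on the
mean).

Determinism: the only randomness is the per-run seeded generator choosing
chain ends; the final unitig set is invariant across seeds (tested over
10 seeds), and within-bucket processing orders keys deterministically so a
fixed seed reproduces a run exactly.

## Long k

k ≤ 64 uses exact string keys. Beyond (or when forced), bucket tables key
on a 128-bit Rabin–Karp polynomial hash of the canonical k-mer — per-base
prime codes {A:2, C:3, G:5, T:7}, a fixed odd 128-bit multiplier, modulus
2^128 — supporting O(1) rolling updates. The map is nonbijective: distinct
k-mers can collide, which is *detected* (the first-seen k-mer text is kept
per entry and compared on every later occurrence; mismatches are counted
and logged, and the CLI warns) but not corrected. Collision correction is
a non-goal.

## Coloring

One color per input file, ids in command-line order. A k-mer's color set
is collected per group (boundary k-mers are counted identically in both
their groups, so either copy is authoritative — asserted when merging),
normalized (sorted, deduplicated), and interned: a 128-bit BLAKE2b hash of
the delta+RLE-encoded set indexes a global table; on a hash hit the stored
set is deep-compared, so a collision raises instead of corrupting. Subset
indices are dense, first-seen-ordered. The abundance threshold counts
occurrences across all files combined. On disk: color sets are delta +
run-length encoded with varints; the color map is chunked (1024 sets per
chunk by default) and zlib-compressed behind a small versioned header;
per-unitig annotations are maximal runs of equal subset indices in the
FASTA description (`C:<idx>:<len>[,...]`). zlib is the package's
compressor choice for all containers; the codec byte in each header leaves
room for alternatives.

## Querying

Each k-mer occurrence — of graph unitigs and of queries alike — is owned
by exactly one bucket, that of its own minimizer (the smaller of its two
window minimizers), so per-bucket counting followed by summation equals a
global membership scan exactly (tested, not just argued). Matching is per
query position: a k-mer occurring twice in a query counts twice; the
alternative (distinct-k-mer counting) would change numbers, so the choice
is fixed and documented rather than exposed as a toggle. Queries shorter
than k report zero totals. Percentages are matched/total × 100 rounded to
two decimals (0.00 for empty); the optional threshold keeps rows with
percentage ≥ threshold. A JSON metadata sidecar written at build time
(k, m, hash, strand mode, colored flag) makes parameter mismatches at
query time detectable errors.

## Reference oracle and what the tests show

The oracle recomputes everything from definitions with no shared extension
code: exact canonical k-mer abundances by position scan; maximal unitigs
by a global greedy over the filtered k-mer set; an independent
node-centric construction (explicit link map + path/cycle decomposition)
whose set equality with the edge-centric output is itself a checked claim;
and a naive per-position query scan. The definitional conditions on unitig
sets and the three structural grouping properties of read splitting are
machine-checked predicates usable against any output.

Synthetic inputs are uniform i.i.d. genomes (1–50 kb in the equivalence
sweep), tiled-plus-random read sets with strand flips and substitution
errors, colored collections with a known backbone/private structure, and
adversarial shapes (circular chromosomes, exact tandem repeats,
low-complexity mosaics, palindrome concatenations, too-short reads).
Problem sizes in the default suite — ~220 fixtures across k ∈ {5, 15, 21,
31, 63} and a ∈ {1, 2}, 100,000-replicate merge simulations, 10,000 codec
round-trips, 100 query batches — were chosen to exercise every code path
at desk scale. What passing shows: exact agreement with the definition on
these input classes, including strand folding, cycles and palindromic
junctions. What it does not show: behavior on real error profiles (indels
are deliberately absent — substitution errors suffice to perturb k-mer
content), on non-uniform base composition, or at the data volumes where
the original disk-based, parallel engineering matters; this implementation
is single-threaded and in-memory (the on-disk bucket format is exercised
but optional), so no wall-clock or memory claims carry over.

## Known limitations

- Even-k palindromic k-mers at group boundaries can break the
  two-records-per-boundary invariant; default parameters use odd k.
- Hashed long-k mode detects but does not correct collisions; a collision
  makes the affected unitigs wrong (with a warning), mirroring the
  documented trade-off of the 128-bit representation.
- The whole build is held in memory; buckets-on-disk exist for the CLI but
  streaming/multi-process execution is out of scope.
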