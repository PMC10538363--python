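# minitig

Construction and batch querying of **compacted, optionally colored, de
Bruijn graphs** — the maximal-unitig representation at the base of genome
assembly, pangenomics and k-mer indexing — implemented as a tested Python
library with a thin command-line interface, and verified end to end against
a brute-force definitional oracle.

## The problem and the algorithm

Given a multiset *R* of DNA sequences (reads or assembled genomes), a k-mer
size *k* and an abundance threshold *a*, the edge-centric de Bruijn graph
has the (k−1)-mers of *R* as nodes and the k-mers occurring at least *a*
times as edges. Its **canonical maximal unitigs** — maximal non-branching
paths, with every k-mer identified with its reverse complement — compress
the graph without losing any k-mer. Formally, the output set *U* satisfies:
every string has length ≥ k; no two distinct strings are reverse
complements; occ<sub>cn</sub>(q, R) ≥ a ⇔ occ<sub>cn</sub>(q, U) ≥ 1 for
every k-mer q; branching (k−1)-mers occur only as string ends; and no end
admits a further extension. These conditions are machine-checked in the
test suite.

The construction merges k-mer counting with unitig building:

1. **Read splitting.** Each sequence is cut into *super-(k−1)-mers*:
   maximal runs of consecutive (k−1)-mers sharing the same **minimizer**
   (minimum rolling hash over their m-mers, reverse-complement-invariant).
   Each segment is extended with the single *linking characters* flanking
   it in the read, so consecutive segments overlap on exactly k characters.
   Segments sharing a minimizer form a group; groups are packed into a
   fixed number of buckets.
2. **In-bucket unitigs.** Per group, a hash table counts every k-mer
   (abundance, source colors, and which side carries a linking character).
   After abundance filtering, unitigs are extended in both directions under
   the both-ways-uniqueness rule; extension stops at k-mers containing a
   linking character — their context continues in exactly one other group —
   and records the stopping k-mer.
3. **Randomized merging.** Endpoint records pair up two-by-two across
   groups and chain the intermediate unitigs together. Instead of a
   union-find, each chain repeatedly picks one of its unsealed ends at
   random and is filed under that end's unitig id; chains meeting in a
   bucket concatenate, provably partner-less ends are sealed. Two chains
   that must merge meet with probability ≥ 1/4 per round (expected four
   tries in the worst case), and the final set is independent of the
   random seed.
4. **Colors.** In colored mode (one color per input file), each k-mer's
   sorted color set is interned through a 128-bit hash into a dense *subset
   index*; sets are stored once, delta + run-length encoded; each unitig
   carries its per-k-mer indices run-length encoded in its FASTA header.
5. **Queries.** Batch FASTA/FASTQ queries are bucketed with the same
   minimizer machinery and matched per position; output is CSV (counts and
   percentages) or, for colored graphs, JSON Lines with per-color counts.

For k > 64, k-mer tables can be keyed by a 128-bit Rabin–Karp hash of the
canonical k-mer (each base a distinct prime); collisions are detected and
reported, not corrected.

## Worked example

```python
from minitig import build_graph
from minitig.synthetic_fixtures import random_genome, sample_reads

genome = random_genome(2000, seed=42)
reads = sample_reads(genome, read_len=80, coverage=3.0, rc_prob=0.5, seed=42)
gb = build_graph([reads], k=11)
print(len(gb.unitigs), sum(len(u.text) for u in gb.unitigs))
print(gb.unitigs[0].text[:60])
```

prints

```
4 2030
CTCCTTTTAACACGACTTGAAGAGTGTGTCTCGTCTGTGCGTGTTCCCGAAAGTGAACCA
```

— the 2 kb genome compacts into 4 maximal unitigs totalling 2030
characters: the genome length plus k−1 = 10 characters per extra unitig,
the breaks caused by 10-mers repeated (up to reverse complement) in the
genome. At k=15 the same input yields a single 2000-character unitig,
since a random 2 kb sequence has no repeated 14-mer. The same graph from
the shell, plus a query:

```
minitig build -k 15 -o graph.fa reads.fq
minitig query --graph graph.fa --queries queries.fa -o hits.csv
```

`hits.csv` holds one line per query: `query,total_kmers,matched,percent`,
e.g. `q0,66,66,100.00` for a query lying entirely inside the graph.

Colored graphs take one file per color and write per-color JSONL query
results:

```
minitig build -k 27 --colors sampleA.fa --colors sampleB.fa -o colored.fa
minitig query --graph colored.fa --queries queries.fa -o hits.jsonl
```

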