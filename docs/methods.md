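# Methods

## Model and estimators

For sequence collections *A*, *B*, let *A^k* be the set of distinct k-mers
(canonical by default: the lexicographic minimum of the k-mer and its reverse
complement). The package estimates the containment index
`C_k(A,B) = |A^k ∩ B^k| / |A^k|` for many k simultaneously and derives the
Jaccard index through the exact identity
`J = |A|·C / (|A| + |B| − |A|·C)` with exact (not approximated) cardinalities.

**Argmin bottom-m sketch.** A single 64-bit hash *h* induces an order on
k-mers; the sketch of *A* at `kmax` is the set of the m *elements* of
`A^kmax` with smallest hash, sorted by (hash, lexicographic). Because the
elements themselves are stored, the length-k prefix of each element is
meaningful, and the multiset of prefixes is the truncated sketch at k.

**Index and streaming.** All reference sketches are inserted into one ternary
search tree whose depth-k node = length-k prefix; nodes carry owning-dataset
labels, and a bloom filter over every stored prefix (for every k of interest)
rejects absent query k-mers cheaply. Streaming the query's k-mers for every k
increments a per-(dataset, k) counter at most once per matched node ("set"
semantics, so the counter estimates the size of a set intersection).
`CI = c_i^k / m`, with the effective element count replacing m when a sketch
is saturated (`|A^kmax| < m`). No bias correction is applied to the reported
values; the diagnostic terms below quantify the bias instead.

**Truncation bias.** Truncation collapses duplicate prefixes, so a truncated
sketch is not a uniform sample of *A^k*. With right-extension counts
`RE^L_P(x) = #{w ∈ P : w[1..k] = x}` over the pool `P = A^{k+L} ∪ B^{k+L}`,
the expected truncated Jaccard estimate equals

```
J_k(A,B) · E[RE | x ∈ A^k ∩ B^k] / E[RE | x ∈ A^k ∪ B^k]
```

computed exactly (rational arithmetic) in `oracle.jaccard_bias_factor`. The
containment analogue multiplies `C_k` by `m/(m−a) · (|S∩B^k|−b)/|S∩B^k|`,
where `a` counts prefixes collapsed by truncating the sketch and `b` is the
overlap-with-B difference between a fresh bottom sketch at k and the truncated
sketch (`oracle.ci_bias_terms`; computing `b` requires the original reference
records to build the fresh sketch).

One subtlety is worth recording. The event "the truncated argmins of *A* and
of *B* coincide" under a single shared hash has *lower* probability than the
closed form above: when the union argmin lies in only one of the sets, the
other set's argmin truncates to the same prefix only with small conditional
probability. The closed form is instead the exact probability that the
truncated argmin of the **union** pool lands in `A^k ∩ B^k` — the event that
also drives the one-sided streaming containment estimate (truncated sample of
*A* found in `B^k`) and hence the CI→JI conversion this package uses.
`oracle.monte_carlo_truncated_jaccard` simulates that union-sample event and
converges to the closed form; this was verified numerically (the
coincidence-event probability can differ by > 0.2 at heavy truncation).

## Hashing and numerics

- Every k-mer (k ≤ 64) is packed exactly into a 128-bit key (two uint64 words,
  2 bits per base, A<C<G<T), so numeric key order equals lexicographic order
  and key equality is exact identity — matching never relies on fingerprints.
- The hash is a splitmix64-style finalizer chain over the packed key, salted
  by (seed, k). Default seed 42, configurable; the seed is recorded in the
  database header and all sketches in one index must share it.
- Ties in hash order are broken lexicographically. Under exact packing,
  distinct equal-length k-mers cannot hash equal through the injective packing
  stage, so the (hash, key) sort order is total; the tie-break is implemented
  regardless.
- Windows containing any non-ACGT character are skipped (counted and logged).
  Input is upper-cased on ingest.
- The vectorised kernel (`_kernel`) computes packed keys and hashes for all
  windows of a chunk with numpy; the scalar definitions in `seqkmer` are the
  reference and the test suite asserts bit-equality. Batch matching goes
  through sorted candidate hashes with exact 128-bit verification of hits, so
  a hash collision cannot create a false match.
- Bias oracles use exact integer/rational arithmetic (`fractions.Fraction`);
  reported floats are exact conversions, and the Eq-level identity is asserted
  internally in rational arithmetic.
- Query orientation: sketch elements are stored as canonical kmax-mers, but a
  prefix of a canonical kmax-mer need not be canonical at length k. Each query
  k-mer is therefore looked up in both orientations and deduplicated on node
  identity, preserving strand-insensitivity. (Equivalently, in the batch
  engine, a literal prefix is matched iff its canonical form occurs among the
  query's canonical k-mers.)

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `m` | 2000 | sketch size; CI standard error ≈ `sqrt(C(1−C)/m)` (≈0.011 at C=0.5) |
| `kmax` | 60 | sketch k-mer length; all queries use k ≤ kmax (≤ 64) |
| k range | 20…60 step 5 | k values answered per query; payload size is independent of how many are chosen |
| hash seed | 42 | shared by all sketches in a database |
| bloom FP rate | 1% | prefilter false-positive target; correctness is unaffected (no false negatives; hits are confirmed in the tree) |
| canonical | on | strand-insensitive k-mers (off available for orientation-free bias analysis) |

## Query engines

`stream_containment` has two interchangeable engines. The `tree` engine walks
the ternary search tree per query k-mer behind the bloom prefilter — the
reference semantics, suitable for desk-scale queries; the tree and filter are
built lazily since large databases never need them. The `vector` engine
computes the identical counters in batch numpy (distinct literal sketch
prefixes whose canonical key occurs in the query) and screens millions of
reads across a full k range in minutes on one CPU; `auto` selects it. A test asserts the two engines produce
identical match counts. Exact query cardinalities |B^k| (needed only for the
JI column) are optional because exact distinct counting over very deep read
sets is memory-heavy; containment needs no query cardinality.

## Synthetic data

`synthdata` emulates the two study designs the estimators are validated on:

- **Community panels**: random ancestor genomes (i.i.d. uniform bases), one
  ancestor per ~5 genomes, each genome a point-mutated descendant with
  per-site substitution probability drawn from U(0.01, 0.10) by default —
  within-genus-like relatedness. Indels (1–3 bp) are available but default to
  off so bias-math validations run on alignment-free substitution structure.
- **Shotgun reads**: fixed-length reads, uniform start positions, either
  strand with probability 1/2, i.i.d. substitution errors (0.5% default),
  abundances proportional to supplied weights (uniform over members here).

Real data differ in ways these generators do not model: repeat structure and
skewed base composition (which raise duplicate-prefix rates and hence
truncation bias), indel-dominated divergence, sequencing error profiles
(quality-correlated, indel-bearing), and uneven coverage. Passing tests
demonstrate correctness of the estimators and the bias theory under the
generative model, not performance claims on any particular real dataset.

## Benchmark sizes

The acceptance benchmark uses 100 references × 500 kb, 20 read-generating
members, 10^6 × 150 bp reads, kmax=60, m=2000, k ∈ {20,…,60} — a
deliberately desk-scale rendition of a metagenomic screen (real reference
panels are 10–100× larger); the package's vectorised engine completes it in
minutes on one CPU. Oracle computations (full enumeration, rational
arithmetic) are exercised on inputs up to ~50 kb and warn above 5 Mb.

## Known limitations

- k ≤ 64 (two-word packing). Raising this would need a third key word.
- No abundance/weighted similarity and no ordered/minimizer variants: weights
  and ordinal structure do not survive truncation.
- Exact distinct counting only (no probabilistic cardinality sketch); exact
  |B^k| over very large query streams is correspondingly expensive.
- The truncated estimator is biased below kmax by design; the bias factor is
  reported by the oracle tools, not corrected in the estimates.
- Databases are rebuilt, not incrementally updated.
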