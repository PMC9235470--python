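# mrsketch

Multi-resolution estimation of k-mer Jaccard and containment indices for
genomic and metagenomic data.

## The problem

k-mer set similarity underlies genome comparison and metagenomic screening:
for sequence collections *A* and *B* with k-mer sets *A^k*, *B^k*,

- Jaccard index `J_k(A,B) = |A^k ∩ B^k| / |A^k ∪ B^k|`
- containment index `C_k(A,B) = |A^k ∩ B^k| / |A^k|`

and the two are interchangeable given cardinalities:
`J = |A|·C / (|A| + |B| − |A|·C)`.

The right k is application-dependent (small k for distant matches, large k for
within-genus discrimination), but classic MinHash sketches commit to one k:
exploring ten k values means sketching a reference database ten times.

`mrsketch` builds **one** sketch per reference at a large `kmax` and answers
queries for **every** `k ≤ kmax`. The trick is to sketch *elements*, not hash
values: the bottom-m sketch stores the m kmax-mers with smallest hash
("argmin" sketch). Stored k-mers can be *truncated* — the length-k prefix of a
kmax-mer is a real k-mer — whereas truncated hash values are meaningless. All
reference sketches live in one k-mer ternary search tree (KTST) whose depth-k
nodes are exactly the truncated sketches; a bloom filter over all stored
prefixes screens query k-mers before tree lookups. Streaming the query once
increments per-(dataset, k) counters `c_i^k` (each distinct matched sketch
prefix counted once), giving `C_k(A_i, B) ≈ c_i^k / m` for the whole k range
in a single pass.

Truncation makes the estimate slightly biased — duplicate prefixes mean a
truncated sketch is no longer a uniform sample of *A^k*. The `oracle` module
computes this bias exactly on desk-scale data: the truncated Jaccard
expectation equals the exact `J_k` times the ratio of mean *right-extension*
counts (number of (k+L)-mers extending a k-mer) over the intersection vs the
union, and the containment analogue decomposes into the duplicate count `a`
and overlap shift `b`. In practice the bias is negligible for moderately
similar data and vanishes at `k = kmax`, where the estimate is bit-identical
to classic MinHash.

## Worked example

```bash
mrsketch simulate --n-genomes 4 --length 20000 --divergence 0.02 --seed 5 \
    --n-reads 2000 --read-length 100 --n-members 2 --out-dir demo
mrsketch build demo/community.fasta --kmax 32 --ks 16:33:8 -m 200 -o demo/db.json
mrsketch query --db demo/db.json --query demo/reads.fastq -o demo/result.csv
```

The build step logs one audit line per dataset:

```
[build] community: 79876 32-mers read, 97 windows skipped (ambiguous base or record boundary), 200/200 sketch elements
```

and the query writes one row per (dataset, k):

```
dataset_id,k,ci_estimate,ji_estimate,matches,sketch_size
community,16,0.700000,0.548754,140,200
community,24,0.625000,0.475221,125,200
community,32,0.540000,0.397274,108,200
```

`ci_estimate` is the fraction of the reference's sketch (truncated to each k)
found among the read k-mers. Here the `community` dataset is one FASTA holding
four related genomes, but reads were simulated from only two members, so a bit
over half of the combined sketch is recovered — more at k=16 where the four
genomes' shared ancestry and read errors still yield matches, less at k=32
where a single error breaks more windows. `ji_estimate` converts CI through
the cardinalities stored at build time plus the exact read-set cardinality.
`matches` is the deduplicated counter `c_i^k` and `sketch_size` the effective
m.

The same machinery is available as a library
(`mrsketch.build_sketch`, `mrsketch.build_index`, `mrsketch.stream_containment`),
including exact oracles (`mrsketch.oracle`) and synthetic data generators
(`mrsketch.synthdata`).

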