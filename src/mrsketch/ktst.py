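"""K-mer ternary search tree index over reference sketches.

All reference sketches (one per dataset, built at a shared kmax and hash seed)
are inserted into a single ternary search tree. A node at depth k represents
the length-k prefix of one or more sketch elements; looking up a k-mer as a
prefix therefore *is* truncation of the stored kmax-mers. Nodes carry the set
of datasets owning at least one element with that prefix, and a bloom filter
over every stored prefix (for every k of interest) screens out absent query
k-mers before the tree is walked.

The Python tree and the bloom filter are built lazily: the batch (vectorised)
query engine in :mod:`mrsketch.estimator` works directly off the sketch key
arrays and never needs them, and for large databases an explicit node-per-base
tree would be needlessly expensive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Set, Tuple

import numpy as np

from . import _kernel
from .seqkmer import HashOrder
from .sketch import ArgMinSketch


class ConfigurationError(ValueError):
    """Sketches disagree on kmax, hash seed, or canonical flag."""


class _Node:
    __slots__ = ("char", "left", "eq", "right", "labels", "node_id")

    def __init__(self, char: str, node_id: int):
        self.char = char
        self.left: Optional[_Node] = None
        self.eq: Optional[_Node] = None
        self.right: Optional[_Node] = None
        self.labels: Set[int] = set()
        self.node_id = node_id


class _TernaryTree:
    """Classic ternary search tree over fixed-length strings with labels."""

    def __init__(self):
        self.root: Optional[_Node] = None
        self._next_id = 0

    def _new_node(self, char: str) -> _Node:
        node = _Node(char, self._next_id)
        self._next_id += 1
        return node

    def insert(self, word: str, label: int) -> None:
        if self.root is None:
            self.root = self._new_node(word[0])
        node = self.root
        i = 0
        while True:
            c = word[i]
            if c < node.char:
                if node.left is None:
                    node.left = self._new_node(c)
                node = node.left
            elif c > node.char:
                if node.right is None:
                    node.right = self._new_node(c)
                node = node.right
            else:
                node.labels.add(label)
                i += 1
                if i == len(word):
                    return
                if node.eq is None:
                    node.eq = self._new_node(word[i])
                node = node.eq

    def find_prefix(self, prefix: str) -> Optional[_Node]:
        """Node spelling ``prefix``, or None if no stored word has it."""
        node = self.root
        i = 0
        while node is not None:
            c = prefix[i]
            if c < node.char:
                node = node.left
            elif c > node.char:
                node = node.right
            else:
                i += 1
                if i == len(prefix):
                    return node
                node = node.eq
        return None


class BloomFilter:
    """Plain bloom filter over packed k-mer keys (no false negatives)."""

    def __init__(self, n_items: int, fp_rate: float, seed: int):
        n_items = max(n_items, 1)
        nbits = int(np.ceil(-n_items * np.log(fp_rate) / (np.log(2) ** 2)))
        self.nbits = max(nbits, 8)
        self.n_hashes = max(1, int(round(self.nbits / n_items * np.log(2))))
        self.bits = np.zeros(self.nbits, dtype=bool)
        self.seed = seed

    def _positions(self, hi: np.ndarray, lo: np.ndarray, k: int) -> np.ndarray:
        h1 = _kernel.hash_keys(hi, lo, k, self.seed ^ 0x5B100F)
        h2 = _kernel.hash_keys(hi, lo, k, self.seed ^ 0x2B100F) | np.uint64(1)
        pos = np.empty((self.n_hashes, hi.size), dtype=np.int64)
        for i in range(self.n_hashes):
            pos[i] = ((h1 + np.uint64(i) * h2) % np.uint64(self.nbits)).astype(np.int64)
        return pos

    def add_keys(self, hi: np.ndarray, lo: np.ndarray, k: int) -> None:
        if hi.size:
            self.bits[self._positions(hi, lo, k).ravel()] = True

    def contains(self, kmer: str) -> bool:
        hi, lo = _kernel.pack_kmer(kmer)
        pos = self._positions(
            np.array([hi], dtype=np.uint64), np.array([lo], dtype=np.uint64), len(kmer)
        )
        return bool(self.bits[pos.ravel()].all())


@dataclass
class QueryCounters:
    """Per (dataset, k) sets of matched node identities; c_i^k = set size.

    Set semantics (each distinct matched sketch prefix counted once, however
    often it recurs in the query) make the counter an estimate of the size of
    a set intersection rather than a match multiplicity.
    """

    matched: Dict[Tuple[str, int], Set[int]] = field(default_factory=dict)

    def record(self, dataset_id: str, k: int, node_id: int) -> None:
        self.matched.setdefault((dataset_id, k), set()).add(node_id)

    def count(self, dataset_id: str, k: int) -> int:
        return len(self.matched.get((dataset_id, k), ()))


class KtstIndex:
    """Prefix-truncatable index over the sketches of N datasets."""

    def __init__(
        self,
        sketches: Sequence[ArgMinSketch],
        k_range: Sequence[int],
        bloom_fp_rate: float = 0.01,
    ):
        if not sketches:
            raise ConfigurationError("cannot build an index from zero sketches")
        kmax = sketches[0].kmax
        seed = sketches[0].seed
        canonical = sketches[0].canonical
        for sk in sketches:
            if (sk.kmax, sk.seed, sk.canonical) != (kmax, seed, canonical):
                raise ConfigurationError(
                    "all sketches must share kmax, hash seed and canonical flag"
                )
        ids = [sk.dataset_id for sk in sketches]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate dataset ids in index")
        k_range = sorted(set(int(k) for k in k_range))
        if not k_range or k_range[0] < 1 or k_range[-1] > kmax:
            raise ConfigurationError("k_range must be a non-empty subset of [1, kmax]")
        self.kmax = kmax
        self.seed = seed
        self.canonical = canonical
        self.k_range = k_range
        self.sketches = list(sketches)
        self.dataset_ids = ids
        self.order = HashOrder(seed=seed)
        self.bloom_fp_rate = bloom_fp_rate
        self._tree: Optional[_TernaryTree] = None
        self._bloom: Optional[BloomFilter] = None

    # -- lazy structures ----------------------------------------------------
    @property
    def tree(self) -> _TernaryTree:
        if self._tree is None:
            tree = _TernaryTree()
            pairs = [
                (el, i)
                for i, sk in enumerate(self.sketches)
                for el in sk.elements
            ]
            # seeded shuffle avoids degenerate depth on sorted insertion
            rng = np.random.default_rng(int(_kernel.mix64(np.uint64(self.seed ^ 0x7EE5))))
            for j in rng.permutation(len(pairs)):
                word, label = pairs[j]
                tree.insert(word, label)
            self._tree = tree
        return self._tree

    @property
    def bloom(self) -> BloomFilter:
        if self._bloom is None:
            n_items = sum(len(sk.elements) for sk in self.sketches) * len(self.k_range)
            bloom = BloomFilter(n_items, self.bloom_fp_rate, seed=self.seed)
            for sk in self.sketches:
                hi, lo = sk.element_keys()
                for k in self.k_range:
                    thi, tlo = _kernel.truncate_keys(hi, lo, self.kmax, k)
                    uhi, ulo = _kernel.unique_keys(thi, tlo)
                    bloom.add_keys(uhi, ulo, k)
            self._bloom = bloom
        return self._bloom

    # -- per-dataset truncated prefix keys (vector engine) ------------------
    def truncated_prefix_keys(self, k: int):
        """For each dataset: distinct literal prefix keys of its elements at k."""
        out = []
        for sk in self.sketches:
            hi, lo = sk.element_keys()
            thi, tlo = _kernel.truncate_keys(hi, lo, self.kmax, k)
            out.append(_kernel.unique_keys(thi, tlo))
        return out


def build_index(
    sketches: Sequence[ArgMinSketch],
    k_range: Sequence[int],
    bloom_fp_rate: float = 0.01,
) -> KtstIndex:
    """Assemble the single shared index over all reference sketches."""
    return KtstIndex(sketches, k_range, bloom_fp_rate=bloom_fp_rate)


def prefix_query(index: KtstIndex, kmer: str) -> Set[Tuple[str, int]]:
    """Datasets owning >= 1 sketch element with this exact prefix.

    Returns (dataset_id, node_identity) pairs; the node identity lets the
    caller deduplicate repeated matches of the same truncated sketch element.
    """
    if len(kmer) not in index.k_range:
        raise ValueError(f"query length {len(kmer)} not in index k_range {index.k_range}")
    node = index.tree.find_prefix(kmer)
    if node is None:
        return set()
    return {(index.dataset_ids[i], node.node_id) for i in node.labels}


def passes_prefilter(index: KtstIndex, kmer: str) -> bool:
    """False => the k-mer is certainly not a stored prefix (no false negatives)."""
    if len(kmer) not in index.k_range:
        raise ValueError(f"query length {len(kmer)} not in index k_range {index.k_range}")
    return index.bloom.contains(kmer)


def truncated_prefix_multiset(obj, k: int, dataset_id: Optional[str] = None) -> Dict[str, int]:
    """Multiset of length-k prefixes of sketch elements.

    ``obj`` may be an :class:`ArgMinSketch` or a :class:`KtstIndex` (optionally
    restricted to one dataset). Multiplicities sum to the number of elements;
    the shortfall of distinct keys vs elements is the duplicate count ``a``
    entering the containment-bias decomposition.
    """
    if isinstance(obj, ArgMinSketch):
        elements = obj.elements
        if k > obj.kmax:
            raise ValueError("k exceeds sketch kmax")
    else:
        if k > obj.kmax:
            raise ValueError("k exceeds index kmax")
        if dataset_id is not None:
            elements = obj.sketches[obj.dataset_ids.index(dataset_id)].elements
        else:
            elements = [el for sk in obj.sketches for el in sk.elements]
    out: Dict[str, int] = {}
    for el in elements:
        p = el[:k]
        out[p] = out.get(p, 0) + 1
    return out
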