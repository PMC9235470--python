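"""Containment/Jaccard estimation for all k in one pass over the query.

Two query engines produce identical counters:

* ``tree`` — the literal streaming path: every query k-mer is bloom-prefiltered
  and looked up as a prefix in the ternary search tree; matched
  (dataset, node) pairs are deduplicated into per-(dataset, k) sets.
* ``vector`` — a batch formulation of the same quantity: a sketch prefix node
  is matched iff its (canonical) packed key occurs among the query's
  (canonical) k-mer keys, so the counter equals the number of distinct literal
  prefixes of a dataset's elements whose canonical form appears in the query.
  This runs the whole k-range over millions of reads in numpy.

The containment estimate for dataset i at k is c_i^k / m (with the effective
element count replacing m for saturated sketches); the Jaccard index follows
from the cardinality identity J = |A| C / (|A| + |B| - |A| C).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import _kernel
from .ktst import KtstIndex, QueryCounters, passes_prefilter, prefix_query
from .seqkmer import (
    HashOrder,
    SequenceRecord,
    canonical_form,
    iter_windows,
    reverse_complement,
)
from .sketch import ArgMinSketch, _DistinctCounter, _iter_code_chunks, build_sketch

CSV_HEADER = ["dataset_id", "k", "ci_estimate", "ji_estimate", "matches", "sketch_size"]


@dataclass
class SimilarityTable:
    """dataset x k table of containment and Jaccard estimates."""

    df: pd.DataFrame
    metadata: dict

    def cell(self, dataset_id: str, k: int, column: str = "ci_estimate"):
        row = self.df[(self.df.dataset_id == dataset_id) & (self.df.k == k)]
        if row.empty:
            raise KeyError((dataset_id, k))
        return row.iloc[0][column]

    def to_csv(self, path) -> None:
        out = self.df.copy()
        for col in ("ci_estimate", "ji_estimate"):
            out[col] = out[col].map(
                lambda v: "" if v is None or (isinstance(v, float) and math.isnan(v)) else f"{v:.6f}"
            )
        out.to_csv(path, index=False, columns=CSV_HEADER)


def ji_from_ci(ci: float, card_A: int, card_B: int) -> float:
    """Convert a containment estimate of A in B to a Jaccard estimate.

    Exact algebraic identity given the two cardinalities; the output is
    clipped to [0, 1] to absorb estimator noise.
    """
    if card_A < 1 or card_B < 1:
        raise ValueError("cardinalities must be positive")
    if not 0.0 <= ci <= 1.0:
        raise ValueError("containment must be within [0, 1]")
    inter = card_A * ci
    denom = card_A + card_B - inter
    if denom <= 0:
        return 1.0
    return min(1.0, max(0.0, inter / denom))


# ---------------------------------------------------------------------------
# vectorised candidate matching

_KEYDT = np.dtype([("hi", np.uint64), ("lo", np.uint64)])


def _as_struct(hi: np.ndarray, lo: np.ndarray) -> np.ndarray:
    arr = np.empty(hi.size, dtype=_KEYDT)
    arr["hi"] = hi
    arr["lo"] = lo
    return arr


def _find_keys(shi: np.ndarray, slo: np.ndarray, qhi: np.ndarray, qlo: np.ndarray) -> np.ndarray:
    """Indices of query keys within a sorted-unique key array (must be present)."""
    return np.searchsorted(_as_struct(shi, slo), _as_struct(qhi, qlo))


class _CandidateSet:
    """Sorted candidate keys at one k, matched against query windows by hash.

    Matching goes through the 64-bit hash (sorted, searchsorted) and verifies
    hits on the exact 128-bit key, so hash collisions cannot create false
    matches; in the (astronomically unlikely) event of duplicate candidate
    hashes a dict fallback resolves them exactly.
    """

    def __init__(self, hi: np.ndarray, lo: np.ndarray, k: int, seed: int):
        self.hi, self.lo = hi, lo
        self.k = k
        h = _kernel.hash_keys(hi, lo, k, seed)
        order = np.argsort(h, kind="stable")
        self.h_sorted = h[order]
        self.perm = order
        self._dup_lookup = None
        if hi.size > 1 and bool(np.any(self.h_sorted[1:] == self.h_sorted[:-1])):
            self._dup_lookup = {
                (int(a), int(b)): i for i, (a, b) in enumerate(zip(hi, lo))
            }

    def match(self, qhi: np.ndarray, qlo: np.ndarray, qh: np.ndarray, presence: np.ndarray):
        if qh.size == 0 or self.h_sorted.size == 0:
            return
        pos = np.searchsorted(self.h_sorted, qh)
        pos[pos == self.h_sorted.size] = 0  # will fail the equality check
        hit = self.h_sorted[pos] == qh
        if not hit.any():
            return
        idx = self.perm[pos[hit]]
        ok = (self.hi[idx] == qhi[hit]) & (self.lo[idx] == qlo[hit])
        presence[idx[ok]] = True
        if self._dup_lookup is not None and not ok.all():
            for a, b in zip(qhi[hit][~ok], qlo[hit][~ok]):
                j = self._dup_lookup.get((int(a), int(b)))
                if j is not None:
                    presence[j] = True


def screen_query(
    candidates: Dict[int, Tuple[np.ndarray, np.ndarray]],
    query: Iterable[SequenceRecord],
    canonical: bool,
    seed: int,
    collect_cardinalities: bool = False,
    batch_bases: int = 3_000_000,
):
    """One streaming pass of the query against per-k candidate key sets.

    Returns (presence, cardinalities, window_counts): presence[k] is a boolean
    array aligned with candidates[k]; cardinalities[k] is the exact distinct
    (canonical) k-mer count of the query when requested, else None.
    """
    ks = sorted(candidates)
    cand_sets = {k: _CandidateSet(candidates[k][0], candidates[k][1], k, seed) for k in ks}
    presence = {k: np.zeros(candidates[k][0].size, dtype=bool) for k in ks}
    counters = {k: _DistinctCounter() for k in ks} if collect_cardinalities else None
    window_counts = {k: 0 for k in ks}
    overlap = max(ks) - 1
    for chunk in _iter_code_chunks(query, overlap=overlap, chunk_bases=batch_bases):
        ps = _kernel.PackedSeq(chunk)
        for k in ks:
            hi, lo, _ = _kernel.window_keys(ps, k, canonical)
            window_counts[k] += hi.size
            if hi.size == 0:
                continue
            qh = _kernel.hash_keys(hi, lo, k, seed)
            cand_sets[k].match(hi, lo, qh, presence[k])
            if counters is not None:
                counters[k].update(hi, lo)
    cards = {k: (counters[k].count() if counters else None) for k in ks}
    return presence, cards, window_counts


# ---------------------------------------------------------------------------
# streaming containment against a KTST index

def _table_from_counts(
    index_sketches: List[ArgMinSketch],
    ks: Sequence[int],
    counts: Dict[Tuple[str, int], int],
    query_cards: Dict[int, Optional[int]],
    metadata: dict,
) -> SimilarityTable:
    rows = []
    for sk in index_sketches:
        for k in ks:
            c = counts.get((sk.dataset_id, k), 0)
            m_eff = sk.m_effective
            if not 0 <= c <= m_eff:
                raise AssertionError("counter out of [0, m] range")
            ci = c / m_eff
            card_a = sk.cardinalities.get(k)
            card_b = query_cards.get(k)
            ji = (
                ji_from_ci(ci, card_a, card_b)
                if card_a and card_b
                else float("nan")
            )
            rows.append(
                {
                    "dataset_id": sk.dataset_id,
                    "k": k,
                    "ci_estimate": ci,
                    "ji_estimate": ji,
                    "matches": c,
                    "sketch_size": m_eff,
                }
            )
    df = pd.DataFrame(rows, columns=CSV_HEADER)
    return SimilarityTable(df=df, metadata=metadata)


def _stream_tree(
    index: KtstIndex,
    query: Iterable[SequenceRecord],
    ks: Sequence[int],
    prefilter: bool,
    query_cardinalities: bool,
):
    counters = QueryCounters()
    card_sets: Dict[int, set] = {k: set() for k in ks}
    window_counts = {k: 0 for k in ks}
    for rec in query:
        for k in ks:
            for w in iter_windows(rec.seq, k):
                window_counts[k] += 1
                if index.canonical:
                    q = canonical_form(w)
                    lookups = {q, reverse_complement(q)}
                else:
                    q = w
                    lookups = {w}
                if query_cardinalities:
                    card_sets[k].add(q)
                for lk in lookups:
                    if prefilter and not passes_prefilter(index, lk):
                        continue
                    for ds, node in prefix_query(index, lk):
                        counters.record(ds, k, node)
    counts = {
        (ds, k): counters.count(ds, k) for ds in index.dataset_ids for k in ks
    }
    cards = {k: (len(card_sets[k]) if query_cardinalities else None) for k in ks}
    return counts, cards, window_counts


def truncation_match_keys(index: KtstIndex, k: int) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Per dataset: the keys a query k-mer set is matched against at k.

    One key per distinct literal length-k prefix of the dataset's sketch
    elements (== per depth-k tree node), canonicalized when the index is
    canonical so that matching is strand-insensitive.
    """
    out = []
    for phi, plo in index.truncated_prefix_keys(k):
        if index.canonical:
            out.append(_kernel.canonical_keys(phi, plo, k))
        else:
            out.append((phi, plo))
    return out


def _stream_vector(
    index: KtstIndex,
    query: Iterable[SequenceRecord],
    ks: Sequence[int],
    query_cardinalities: bool,
    batch_bases: int,
):
    candidates: Dict[int, Tuple[np.ndarray, np.ndarray]] = {}
    maps: Dict[int, List[np.ndarray]] = {}
    for k in ks:
        match_keys = truncation_match_keys(index, k)
        ghi, glo = _kernel.merge_unique(
            [mk[0] for mk in match_keys], [mk[1] for mk in match_keys]
        )
        candidates[k] = (ghi, glo)
        maps[k] = [_find_keys(ghi, glo, mhi, mlo) for mhi, mlo in match_keys]
    presence, cards, window_counts = screen_query(
        candidates,
        query,
        canonical=index.canonical,
        seed=index.seed,
        collect_cardinalities=query_cardinalities,
        batch_bases=batch_bases,
    )
    counts = {}
    for k in ks:
        for sk_obj, idx in zip(index.sketches, maps[k]):
            counts[(sk_obj.dataset_id, k)] = int(presence[k][idx].sum())
    return counts, cards, window_counts


def stream_containment(
    index: KtstIndex,
    query: Iterable[SequenceRecord],
    k_range: Optional[Sequence[int]] = None,
    engine: str = "auto",
    prefilter: bool = True,
    query_cardinalities: bool = True,
    query_label: str = "query",
    batch_bases: int = 3_000_000,
) -> SimilarityTable:
    """Estimate C_k(A_i, query) for every dataset and every k in one pass.

    ``engine="tree"`` walks the ternary search tree per query k-mer (the
    reference semantics, suited to desk-scale queries); ``"vector"`` (the
    ``"auto"`` default) computes the identical counters in batch numpy and
    scales to read sets of millions.
    """
    ks = sorted(set(k_range)) if k_range is not None else list(index.k_range)
    if not set(ks).issubset(index.k_range):
        raise ValueError(f"k_range {ks} not a subset of index k_range {index.k_range}")
    if engine == "auto":
        engine = "vector"
    if engine == "tree":
        query = list(query)
        counts, cards, window_counts = _stream_tree(
            index, query, ks, prefilter, query_cardinalities
        )
    elif engine == "vector":
        counts, cards, window_counts = _stream_vector(
            index, query, ks, query_cardinalities, batch_bases
        )
    else:
        raise ValueError(f"unknown engine {engine!r}")
    if any(window_counts[k] == 0 for k in ks):
        empty = [k for k in ks if window_counts[k] == 0]
        raise ValueError(f"query yields no valid k-mer at k={empty}")
    metadata = {
        "kmax": index.kmax,
        "seed": index.seed,
        "canonical": index.canonical,
        "query_label": query_label,
        "engine": engine,
        "query_cardinalities": cards,
        "query_windows": window_counts,
    }
    return _table_from_counts(index.sketches, ks, counts, cards, metadata)


# ---------------------------------------------------------------------------
# classic fixed-k MinHash baselines

def minhash_containment_table(
    sketches_by_k: Dict[int, List[ArgMinSketch]],
    query: Iterable[SequenceRecord],
    query_cardinalities: bool = False,
    batch_bases: int = 3_000_000,
) -> SimilarityTable:
    """Containment of each per-k bottom sketch in the query, one query pass.

    Every sketch in ``sketches_by_k[k]`` must have been built at kmax == k
    (no truncation); this is the classic fixed-k comparator.
    """
    any_sk = next(iter(sketches_by_k.values()))[0]
    canonical, seed = any_sk.canonical, any_sk.seed
    candidates = {}
    maps = {}
    for k, sks in sketches_by_k.items():
        for sk in sks:
            if sk.kmax != k or sk.canonical != canonical or sk.seed != seed:
                raise ValueError("baseline sketches must be built at kmax == k with one seed")
        keys = [sk.element_keys() for sk in sks]
        ghi, glo = _kernel.merge_unique([h for h, _ in keys], [l for _, l in keys])
        candidates[k] = (ghi, glo)
        maps[k] = [_find_keys(ghi, glo, h, l) for h, l in keys]
    presence, cards, window_counts = screen_query(
        candidates,
        query,
        canonical=canonical,
        seed=seed,
        collect_cardinalities=query_cardinalities,
        batch_bases=batch_bases,
    )
    rows = []
    for k in sorted(sketches_by_k):
        if window_counts[k] == 0:
            raise ValueError(f"query yields no valid k-mer at k={k}")
        for sk, idx in zip(sketches_by_k[k], maps[k]):
            c = int(presence[k][idx].sum())
            m_eff = sk.m_effective
            ci = c / m_eff
            card_a = sk.cardinalities.get(k)
            card_b = cards.get(k)
            ji = ji_from_ci(ci, card_a, card_b) if card_a and card_b else float("nan")
            rows.append(
                {
                    "dataset_id": sk.dataset_id,
                    "k": k,
                    "ci_estimate": ci,
                    "ji_estimate": ji,
                    "matches": c,
                    "sketch_size": m_eff,
                }
            )
    df = pd.DataFrame(rows, columns=CSV_HEADER)
    return SimilarityTable(df=df, metadata={"seed": seed, "canonical": canonical})


def minhash_containment_baseline(
    records_A: Iterable[SequenceRecord],
    query_B: Iterable[SequenceRecord],
    k: int,
    m: int,
    order: HashOrder,
    canonical: bool = True,
) -> float:
    """Classic containment MinHash at a single fixed k (fresh bottom sketch)."""
    sk = build_sketch(
        list(records_A), kmax=k, m=m, order=order, canonical=canonical, k_range=()
    )
    table = minhash_containment_table({k: [sk]}, query_B)
    return float(table.df.iloc[0]["ci_estimate"])


def minhash_jaccard_baseline(
    records_A: Iterable[SequenceRecord],
    records_B: Iterable[SequenceRecord],
    k: int,
    m: int,
    order: HashOrder,
    canonical: bool = False,
) -> float:
    """Bottom-m hash-value Jaccard estimator.

    |S_m(A u B) n S_m(A) n S_m(B)| over the union-sketch size; the
    denominator is min(m, |A^k u B^k|) so that saturated sketches (sets
    smaller than m) still give exact answers.
    """

    def bottom_hashes(records) -> np.ndarray:
        parts = []
        for chunk in _iter_code_chunks(records, overlap=k - 1, chunk_bases=4_000_000):
            ps = _kernel.PackedSeq(chunk)
            hi, lo, _ = _kernel.window_keys(ps, k, canonical)
            parts.append(_kernel.hash_keys(hi, lo, k, order.seed))
        if not parts:
            return np.empty(0, dtype=np.uint64)
        return np.unique(np.concatenate(parts))

    ha = bottom_hashes(list(records_A))
    hb = bottom_hashes(list(records_B))
    if ha.size == 0 or hb.size == 0:
        raise ValueError("both inputs must contain at least one valid k-mer")
    sa = ha[:m]
    sb = hb[:m]
    su = np.unique(np.concatenate([ha, hb]))[:m]
    inter = np.intersect1d(su, np.intersect1d(sa, sb, assume_unique=True), assume_unique=True)
    return inter.size / su.size
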