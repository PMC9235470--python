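"""Brute-force ground truth and closed-form truncation-bias computations.

Everything here works on full k-mer enumerations (exact set arithmetic on
strings) and exact rational arithmetic, so it serves as the independent
reference against which the sketch estimators are validated. Intended for
desk-scale inputs (up to a few Mb); a size warning guards larger calls.

The central quantity is the *right extension* count RE^L_P(x): the number of
(k+L)-mers in a pool P that have the k-mer x as a prefix. Truncating a
kmax-mer sketch to length k is equivalent to sampling k-mers with probability
proportional to their right-extension counts rather than uniformly, which
multiplies the Jaccard index by the ratio of the mean right extension over the
intersection to the mean over the union. The containment analogue decomposes
into the duplicate count ``a`` (prefixes collapsed by truncation) and the
overlap shift ``b`` between the fresh bottom sketch at k and the truncated
sketch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, Iterable, List, Optional

import numpy as np

from . import _kernel
from .seqkmer import HashOrder, KmerSet, SequenceRecord, canonical_form, enumerate_kmers
from .sketch import ArgMinSketch, build_sketch

_SIZE_WARN_BP = 5_000_000


@dataclass
class BiasReport:
    """Exact truncated index, exact index at k, and the bias decomposition."""

    k: int
    L: int
    ji_exact_at_k: float
    ji_truncated_closed_form: float
    bias_factor_ji: float
    mean_re_intersection: float
    mean_re_union: float
    defined: bool = True
    a: Optional[int] = None
    b: Optional[int] = None


def _warn_if_large(records: List[SequenceRecord]) -> None:
    total = sum(len(r) for r in records)
    if total > _SIZE_WARN_BP:
        warnings.warn(
            f"oracle called on {total} bp; brute-force enumeration may be slow",
            stacklevel=3,
        )


def exact_jaccard(
    records_A: Iterable[SequenceRecord],
    records_B: Iterable[SequenceRecord],
    k: int,
    canonical: bool = False,
) -> float:
    """J_k(A, B) by full enumeration."""
    records_A, records_B = list(records_A), list(records_B)
    _warn_if_large(records_A + records_B)
    a = enumerate_kmers(records_A, k, canonical).kmers
    b = enumerate_kmers(records_B, k, canonical).kmers
    union = a | b
    if not union:
        raise ValueError("both k-mer sets are empty")
    return len(a & b) / len(union)


def exact_containment(
    records_A: Iterable[SequenceRecord],
    records_B: Iterable[SequenceRecord],
    k: int,
    canonical: bool = False,
) -> float:
    """C_k(A, B) = |A^k n B^k| / |A^k| by full enumeration."""
    records_A, records_B = list(records_A), list(records_B)
    _warn_if_large(records_A + records_B)
    a = enumerate_kmers(records_A, k, canonical).kmers
    if not a:
        raise ValueError("A has no k-mers; containment undefined")
    b = enumerate_kmers(records_B, k, canonical).kmers
    return len(a & b) / len(a)


def right_extensions(x: str, L: int, pool: KmerSet) -> int:
    """RE^L_pool(x): pool elements of length len(x)+L having x as prefix."""
    if pool.k != len(x) + L:
        raise ValueError(f"pool holds {pool.k}-mers; expected {len(x) + L}-mers")
    return sum(1 for w in pool.kmers if w.startswith(x))


def _re_table(pool_kmers: set, k: int) -> Dict[str, int]:
    """Right-extension counts of every k-prefix occurring in the pool."""
    out: Dict[str, int] = {}
    for w in pool_kmers:
        p = w[:k]
        out[p] = out.get(p, 0) + 1
    return out


def truncated_jaccard_closed_form(
    records_A: Iterable[SequenceRecord],
    records_B: Iterable[SequenceRecord],
    k: int,
    L: int,
    canonical: bool = False,
) -> float:
    """Exact expected value of the (k+L -> k)-truncated m=1 Jaccard estimator.

    sum_{x in A^k n B^k} RE^L_{A^{k+L} u B^{k+L}}(x) / |A^{k+L} u B^{k+L}|,
    evaluated by full enumeration (no hashing, no sampling).
    """
    records_A, records_B = list(records_A), list(records_B)
    _warn_if_large(records_A + records_B)
    ak = enumerate_kmers(records_A, k, canonical).kmers
    bk = enumerate_kmers(records_B, k, canonical).kmers
    pool = (
        enumerate_kmers(records_A, k + L, canonical).kmers
        | enumerate_kmers(records_B, k + L, canonical).kmers
    )
    if not pool:
        raise ValueError("the (k+L)-mer pool is empty")
    re = _re_table(pool, k)
    num = sum(re.get(x, 0) for x in ak & bk)
    return float(Fraction(num, len(pool)))


def jaccard_bias_factor(
    records_A: Iterable[SequenceRecord],
    records_B: Iterable[SequenceRecord],
    k: int,
    L: int,
    canonical: bool = False,
) -> BiasReport:
    """Multiplicative truncation-bias factor of the Jaccard index.

    factor = E_{x in A^k n B^k}[RE(x)] / E_{x in A^k u B^k}[RE(x)], with RE
    taken over the union pool at k+L. Verifies internally (in exact rational
    arithmetic) that truncated JI == exact JI at k x factor.
    """
    records_A, records_B = list(records_A), list(records_B)
    _warn_if_large(records_A + records_B)
    ak = enumerate_kmers(records_A, k, canonical).kmers
    bk = enumerate_kmers(records_B, k, canonical).kmers
    inter, union = ak & bk, ak | bk
    pool = (
        enumerate_kmers(records_A, k + L, canonical).kmers
        | enumerate_kmers(records_B, k + L, canonical).kmers
    )
    re = _re_table(pool, k)
    ji_exact = Fraction(len(inter), len(union))
    ji_trunc = Fraction(sum(re.get(x, 0) for x in inter), len(pool))
    if not inter:
        return BiasReport(
            k=k,
            L=L,
            ji_exact_at_k=0.0,
            ji_truncated_closed_form=float(ji_trunc),
            bias_factor_ji=float("nan"),
            mean_re_intersection=float("nan"),
            mean_re_union=float(Fraction(len(pool), len(union))),
            defined=False,
        )
    mean_inter = Fraction(sum(re.get(x, 0) for x in inter), len(inter))
    # every pool element's k-prefix lies in the union, so the RE sum over the
    # union must equal |pool|: an internal consistency check of the derivation
    re_sum_union = sum(re.get(x, 0) for x in union)
    assert re_sum_union == len(pool), "right-extension bookkeeping violated"
    mean_union = Fraction(len(pool), len(union))
    factor = mean_inter / mean_union
    assert ji_trunc == ji_exact * factor, "bias identity violated in exact arithmetic"
    return BiasReport(
        k=k,
        L=L,
        ji_exact_at_k=float(ji_exact),
        ji_truncated_closed_form=float(ji_trunc),
        bias_factor_ji=float(factor),
        mean_re_intersection=float(mean_inter),
        mean_re_union=float(mean_union),
    )


def exact_truncated_containment(
    records_A: Iterable[SequenceRecord],
    records_B: Iterable[SequenceRecord],
    k: int,
    kmax: int,
    canonical: bool = False,
) -> float:
    """Full-set truncated containment: |(A^kmax)_{1..k} n B^k| / |A^kmax|.

    The saturated-sketch (m >= |A^kmax|) limit of the streaming estimator: the
    distinct k-prefixes of all kmax-mers of A, matched against B's k-mers
    (strand-insensitively in canonical mode), over the kmax-mer count.
    """
    records_A, records_B = list(records_A), list(records_B)
    _warn_if_large(records_A + records_B)
    akmax = enumerate_kmers(records_A, kmax, canonical).kmers
    if not akmax:
        raise ValueError("A has no kmax-mers")
    bk = enumerate_kmers(records_B, k, canonical).kmers
    prefixes = {w[:k] for w in akmax}
    if canonical:
        matched = sum(1 for p in prefixes if canonical_form(p) in bk)
    else:
        matched = sum(1 for p in prefixes if p in bk)
    return matched / len(akmax)


def ci_bias_terms(
    sketch: ArgMinSketch,
    records_B: Iterable[SequenceRecord],
    k: int,
    records_A: Optional[Iterable[SequenceRecord]] = None,
) -> BiasReport:
    """Duplicate count ``a`` and overlap shift ``b`` of the truncated-CI bias.

    a = (sketch size) - (distinct k-prefixes of the sketch elements): the
    number of duplicates collapsed by truncation. b compares the overlap with
    B^k of a fresh bottom sketch at k against that of the truncated sketch;
    it requires the original reference records (``records_A``) to build the
    fresh sketch and is None when they are not supplied.
    """
    if k > sketch.kmax:
        raise ValueError("k exceeds sketch kmax")
    records_B = list(records_B)
    L = sketch.kmax - k
    trunc_prefixes = {el[:k] for el in sketch.elements}
    a = sketch.m_effective - len(trunc_prefixes)
    bk = enumerate_kmers(records_B, k, sketch.canonical).kmers

    def overlap(kmers: Iterable[str]) -> int:
        if sketch.canonical:
            return sum(1 for x in kmers if canonical_form(x) in bk)
        return sum(1 for x in kmers if x in bk)

    trunc_overlap = overlap(trunc_prefixes)
    b: Optional[int] = None
    if records_A is not None:
        fresh = build_sketch(
            list(records_A),
            kmax=k,
            m=sketch.m,
            order=HashOrder(seed=sketch.seed),
            canonical=sketch.canonical,
            k_range=(),
        )
        b = overlap(fresh.elements) - trunc_overlap
    return BiasReport(
        k=k,
        L=L,
        ji_exact_at_k=float("nan"),
        ji_truncated_closed_form=float("nan"),
        bias_factor_ji=float("nan"),
        mean_re_intersection=float("nan"),
        mean_re_union=float("nan"),
        a=a,
        b=b,
    )


def monte_carlo_truncated_jaccard(
    records_A: Iterable[SequenceRecord],
    records_B: Iterable[SequenceRecord],
    k: int,
    L: int,
    n_seeds: int,
    base_seed: int = 0,
    canonical: bool = False,
):
    """m=1 truncated-collision frequency over many hash seeds.

    Simulates the sampling process the closed form describes: for each seed,
    the argmin (k+L)-mer of the union pool A^{k+L} u B^{k+L} is truncated to
    length k and counted as a collision when the truncated k-mer belongs to
    A^k n B^k (the event whose per-element probability drives both the
    union-sketch Jaccard estimate and, one-sidedly, the streaming containment
    estimate). Returns (frequency, standard_error).
    """
    records_A, records_B = list(records_A), list(records_B)
    ak = enumerate_kmers(records_A, k, canonical).kmers
    bk = enumerate_kmers(records_B, k, canonical).kmers
    inter = ak & bk
    pool = sorted(
        enumerate_kmers(records_A, k + L, canonical).kmers
        | enumerate_kmers(records_B, k + L, canonical).kmers
    )
    if not pool:
        raise ValueError("empty (k+L)-mer pool")

    hi = np.empty(len(pool), dtype=np.uint64)
    lo = np.empty(len(pool), dtype=np.uint64)
    for i, w in enumerate(pool):
        h, l = _kernel.pack_kmer(w)
        hi[i] = h
        lo[i] = l
    hits = 0
    for s in range(n_seeds):
        h = _kernel.hash_keys(hi, lo, k + L, base_seed + s)
        w = pool[int(np.argmin(h))]
        if w[:k] in inter:
            hits += 1
    freq = hits / n_seeds
    se = float(np.sqrt(max(freq * (1 - freq), 1e-12) / n_seeds))
    return freq, se
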