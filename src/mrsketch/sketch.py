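"""Bottom-m k-mer sketches that store elements (not hash values).

Storing the winning k-mers themselves, rather than their hash values, is what
makes prefix truncation possible downstream: the length-k prefix of a stored
kmax-mer is a meaningful k-mer, whereas the truncation of a hash value is
meaningless. The sketch of a dataset is the m distinct kmax-mers with the
smallest hash under the shared :class:`~mrsketch.seqkmer.HashOrder`, sorted by
(hash, lexicographic) ascending.

Construction is streaming: input records are processed in bounded chunks and
only the current best m candidates are retained, so sketch memory is
proportional to m (plus one chunk), not to the k-mer set size. Exact per-k
cardinalities, when requested, necessarily hold a distinct-key set per k and
are intended for desk-scale reference data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from . import _kernel
from .seqkmer import HashOrder, SequenceRecord

_SEP = np.array([_kernel.INVALID], dtype=np.uint8)


class EmptySketchError(ValueError):
    """No valid kmax-mer was found in the input."""


@dataclass
class ArgMinSketch:
    """The m elements of a kmax-mer set with smallest hash, plus cardinalities.

    ``elements`` are DNA strings of length kmax sorted ascending by
    (hash value, lexicographic); ``cardinalities`` maps k to the exact count
    of distinct k-mers of the source data.
    """

    dataset_id: str
    kmax: int
    m: int
    canonical: bool
    seed: int
    elements: list
    cardinalities: dict

    _keys: Optional[tuple] = field(default=None, repr=False, compare=False)

    @property
    def m_effective(self) -> int:
        """min(m, |A^kmax|): the actual sketch size (estimator denominator)."""
        return len(self.elements)

    def element_keys(self):
        """Packed (hi, lo) uint64 arrays of the elements (cached)."""
        if self._keys is None:
            hi = np.empty(len(self.elements), dtype=np.uint64)
            lo = np.empty(len(self.elements), dtype=np.uint64)
            for i, e in enumerate(self.elements):
                h, l = _kernel.pack_kmer(e)
                hi[i] = h
                lo[i] = l
            self._keys = (hi, lo)
        return self._keys

    def element_hashes(self) -> np.ndarray:
        hi, lo = self.element_keys()
        return _kernel.hash_keys(hi, lo, self.kmax, self.seed)

    def to_dict(self) -> dict:
        return {
            "id": self.dataset_id,
            "kmax": self.kmax,
            "m": self.m,
            "canonical": self.canonical,
            "seed": self.seed,
            "elements": list(self.elements),
            "cardinalities": {str(k): v for k, v in self.cardinalities.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArgMinSketch":
        return cls(
            dataset_id=d["id"],
            kmax=int(d["kmax"]),
            m=int(d["m"]),
            canonical=bool(d["canonical"]),
            seed=int(d["seed"]),
            elements=list(d["elements"]),
            cardinalities={int(k): int(v) for k, v in d["cardinalities"].items()},
        )


def _iter_code_chunks(
    records: Iterable[SequenceRecord], overlap: int, chunk_bases: int
):
    """Yield uint8 code chunks covering every window of every record.

    Records are joined with an invalid separator code (windows never cross
    record boundaries); records longer than a chunk are split with ``overlap``
    shared bases so no window is lost (duplicates are removed downstream).
    """
    parts: list = []
    size = 0
    for rec in records:
        codes = _kernel.encode(rec.seq)
        n = codes.size
        pos = 0
        step = max(chunk_bases - overlap, 1)
        while pos == 0 or pos < n - overlap:
            piece = codes[pos : pos + chunk_bases]
            parts.append(piece)
            parts.append(_SEP)
            size += piece.size + 1
            if size >= chunk_bases:
                yield np.concatenate(parts)
                parts, size = [], 0
            if piece.size < chunk_bases and pos == 0:
                break
            pos += step
    if parts:
        yield np.concatenate(parts)


class _TopM:
    """Running selection of the m smallest-(hash, key) distinct k-mers."""

    def __init__(self, m: int, k: int, seed: int):
        self.m = m
        self.k = k
        self.seed = seed
        self.hi = np.empty(0, dtype=np.uint64)
        self.lo = np.empty(0, dtype=np.uint64)
        self.h = np.empty(0, dtype=np.uint64)

    def update(self, hi: np.ndarray, lo: np.ndarray):
        if hi.size == 0:
            return
        h = _kernel.hash_keys(hi, lo, self.k, self.seed)
        hi = np.concatenate([self.hi, hi])
        lo = np.concatenate([self.lo, lo])
        h = np.concatenate([self.h, h])
        order = np.lexsort((lo, hi, h))
        hi, lo, h = hi[order], lo[order], h[order]
        # equal keys have equal hashes, hence are adjacent after this sort
        keep = np.empty(hi.size, dtype=bool)
        keep[0] = True
        np.not_equal(hi[1:], hi[:-1], out=keep[1:])
        keep[1:] |= lo[1:] != lo[:-1]
        hi, lo, h = hi[keep], lo[keep], h[keep]
        self.hi, self.lo, self.h = hi[: self.m], lo[: self.m], h[: self.m]


class _DistinctCounter:
    """Exact distinct-key counting with periodic merges."""

    def __init__(self):
        self.parts_hi: list = []
        self.parts_lo: list = []
        self._pending = 0

    def update(self, hi: np.ndarray, lo: np.ndarray):
        if hi.size == 0:
            return
        uhi, ulo = _kernel.unique_keys(hi, lo)
        self.parts_hi.append(uhi)
        self.parts_lo.append(ulo)
        self._pending += 1
        if self._pending >= 8:
            self._merge()

    def _merge(self):
        uhi, ulo = _kernel.merge_unique(self.parts_hi, self.parts_lo)
        self.parts_hi, self.parts_lo = [uhi], [ulo]
        self._pending = 0

    def count(self) -> int:
        if not self.parts_hi:
            return 0
        self._merge()
        return self.parts_hi[0].size


def build_sketch(
    records: Iterable[SequenceRecord],
    kmax: int,
    m: int,
    order: HashOrder,
    canonical: bool = True,
    dataset_id: str = "dataset",
    k_range: Optional[Sequence[int]] = None,
    chunk_bases: int = 4_000_000,
) -> ArgMinSketch:
    """Build the argmin-bottom sketch of a dataset at kmax.

    ``k_range`` selects the k values for which exact cardinalities are
    recorded (default: kmax only; pass an empty sequence to skip cardinality
    tracking entirely, e.g. for containment-only workflows).
    """
    if m < 1:
        raise ValueError("sketch size m must be >= 1")
    if not 1 <= kmax <= _kernel.MAX_K:
        raise ValueError(f"kmax must be in [1, {_kernel.MAX_K}]")
    if k_range is None:
        k_range = (kmax,)
    k_range = sorted(set(int(k) for k in k_range))
    if any(k < 1 or k > kmax for k in k_range):
        raise ValueError("cardinality k values must be in [1, kmax]")

    top = _TopM(m, kmax, order.seed)
    counters = {k: _DistinctCounter() for k in k_range}
    n_windows = 0
    n_skipped = 0
    for chunk in _iter_code_chunks(records, overlap=kmax - 1, chunk_bases=chunk_bases):
        ps = _kernel.PackedSeq(chunk)
        hi, lo, skipped = _kernel.window_keys(ps, kmax, canonical)
        n_windows += hi.size
        n_skipped += skipped
        top.update(hi, lo)
        for k in k_range:
            if k == kmax:
                counters[k].update(hi, lo)
            else:
                khi, klo, _ = _kernel.window_keys(ps, k, canonical)
                counters[k].update(khi, klo)

    if top.hi.size == 0:
        raise EmptySketchError(
            f"dataset {dataset_id!r} contains no valid {kmax}-mer"
        )
    elements = [
        _kernel.decode_key(int(h), int(l), kmax) for h, l in zip(top.hi, top.lo)
    ]
    sk = ArgMinSketch(
        dataset_id=dataset_id,
        kmax=kmax,
        m=m,
        canonical=canonical,
        seed=order.seed,
        elements=elements,
        cardinalities={k: c.count() for k, c in counters.items()},
    )
    sk._keys = (top.hi.copy(), top.lo.copy())
    # audit counters for logging; skipped = windows containing an ambiguous
    # base or a record separator (includes chunk-overlap/separator artifacts)
    sk.stats = {
        "kmax_windows": n_windows,
        "kmax_windows_skipped": n_skipped,
        "saturated": len(elements) < m,
    }
    return sk


def build_sketches_multi_k(
    records: Iterable[SequenceRecord],
    ks: Sequence[int],
    m: int,
    order: HashOrder,
    canonical: bool = True,
    dataset_id: str = "dataset",
    chunk_bases: int = 4_000_000,
) -> dict:
    """Fresh bottom-m sketches at several k values in one pass over the input.

    Each returned sketch is exactly what ``build_sketch(records, kmax=k, ...)``
    would produce (a test asserts this); sharing the encoding/packing pass
    makes building a classic per-k sketch panel far cheaper. Cardinalities are
    not tracked.
    """
    ks = sorted(set(int(k) for k in ks))
    if m < 1:
        raise ValueError("sketch size m must be >= 1")
    if any(k < 1 or k > _kernel.MAX_K for k in ks):
        raise ValueError(f"k values must be in [1, {_kernel.MAX_K}]")
    tops = {k: _TopM(m, k, order.seed) for k in ks}
    overlap = max(ks) - 1
    for chunk in _iter_code_chunks(records, overlap=overlap, chunk_bases=chunk_bases):
        ps = _kernel.PackedSeq(chunk)
        for k in ks:
            hi, lo, _ = _kernel.window_keys(ps, k, canonical)
            tops[k].update(hi, lo)
    out = {}
    for k in ks:
        top = tops[k]
        if top.hi.size == 0:
            raise EmptySketchError(f"dataset {dataset_id!r} contains no valid {k}-mer")
        sk = ArgMinSketch(
            dataset_id=dataset_id,
            kmax=k,
            m=m,
            canonical=canonical,
            seed=order.seed,
            elements=[
                _kernel.decode_key(int(h), int(l), k)
                for h, l in zip(top.hi, top.lo)
            ],
            cardinalities={},
        )
        sk._keys = (top.hi.copy(), top.lo.copy())
        out[k] = sk
    return out


def exact_cardinality(
    records: Iterable[SequenceRecord],
    k: int,
    canonical: bool = True,
    chunk_bases: int = 4_000_000,
) -> int:
    """Exact |A^k|: the number of distinct (canonical) k-mers of the records."""
    if k < 1:
        raise ValueError("k must be >= 1")
    counter = _DistinctCounter()
    for chunk in _iter_code_chunks(records, overlap=k - 1, chunk_bases=chunk_bases):
        ps = _kernel.PackedSeq(chunk)
        hi, lo, _ = _kernel.window_keys(ps, k, canonical)
        counter.update(hi, lo)
    return counter.count()
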