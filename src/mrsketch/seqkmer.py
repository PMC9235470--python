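"""Sequence I/O, canonical k-mers, and the hash order shared by all sketches.

All sketching in this package is driven by a single deterministic 64-bit hash
over k-mers (:func:`hash_kmer`, parameterised by :class:`HashOrder`). The hash
is defined over an exact 2-bit packing of the k-mer, so it is collision-free
as an identity for k <= 64 and totally ordered once the lexicographic
tie-break is applied (ties between distinct equal-length k-mers cannot occur
under this construction, but the sort order (hash, kmer) implements the
tie-break regardless).
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
from Bio import SeqIO

from . import _kernel

DEFAULT_SEED = 42

_VALID_BASES = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class AmbiguousBaseError(ValueError):
    """Raised when a k-mer contains a non-ACGT character."""


@dataclass
class SequenceRecord:
    """A named DNA sequence; bases are upper-cased on construction."""

    id: str
    seq: str

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        self.seq = self.seq.upper()

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class HashOrder:
    """Deterministic 64-bit hash order over k-mers.

    Same seed and k-mer always give the same value; remaining ties (impossible
    for distinct k-mers of equal length under exact packing) are broken by
    lexicographic order.
    """

    seed: int = DEFAULT_SEED

    width: int = field(default=64, init=False, repr=False)


def reverse_complement(kmer: str) -> str:
    return kmer.translate(_COMPLEMENT)[::-1]


def canonical_form(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement.

    Idempotent; rejects ambiguous bases so the caller can skip the window.
    """
    if not _VALID_BASES.issuperset(kmer):
        raise AmbiguousBaseError(f"ambiguous base in k-mer {kmer!r}")
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def hash_kmer(kmer: str, order: HashOrder) -> int:
    """64-bit hash of a k-mer; scalar reference for the vectorised kernel."""
    if not kmer:
        raise ValueError("cannot hash an empty k-mer")
    hi, lo = _kernel.pack_kmer(kmer)
    salt = int(_kernel._hash_salt(len(kmer), order.seed))
    return int(_kernel.mix64(np.uint64(hi) ^ _kernel.mix64(np.uint64(lo ^ salt))))


@dataclass
class KmerSet:
    """The set of distinct k-mers of a sequence collection at a fixed k."""

    k: int
    kmers: set
    canonical: bool = False

    def __len__(self) -> int:
        return len(self.kmers)

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.kmers


def iter_windows(seq: str, k: int) -> Iterator[str]:
    """Valid (ACGT-only) k-windows of one sequence, in order."""
    n = len(seq)
    # positions of invalid characters let us skip windows cheaply
    for i in range(n - k + 1):
        w = seq[i : i + k]
        if _VALID_BASES.issuperset(w):
            yield w


def enumerate_kmers(
    records: Iterable[SequenceRecord], k: int, canonical: bool = True
) -> KmerSet:
    """All distinct k-mers over the records (brute-force, desk scale).

    Windows containing an ambiguous base are skipped. The vectorised kernel
    (`_kernel.window_keys`) provides the scalable equivalent; a test asserts
    they enumerate identical sets.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    out: set = set()
    for rec in records:
        for w in iter_windows(rec.seq, k):
            out.add(canonical_form(w) if canonical else w)
    return KmerSet(k=k, kmers=out, canonical=canonical)


# ---------------------------------------------------------------------------
# file reading

def _open_maybe_gzip(path) -> io.TextIOWrapper:
    fh = open(path, "rb")
    magic = fh.read(2)
    fh.seek(0)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=fh))
    return io.TextIOWrapper(fh)


def _sniff_format(handle) -> Optional[str]:
    pos = handle.tell()
    first = handle.read(1)
    handle.seek(pos)
    if first == "":
        return None
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise ValueError(f"cannot detect sequence format from leading {first!r}")


def iter_sequences(path, fmt: Optional[str] = None) -> Iterator[SequenceRecord]:
    """Stream records from a FASTA/FASTQ file (gzip auto-detected)."""
    path = Path(path)
    handle = _open_maybe_gzip(path)
    try:
        if fmt is None:
            fmt = _sniff_format(handle)
        if fmt is None:  # empty file
            return
        index = 0
        parser = SeqIO.parse(handle, fmt)
        while True:
            try:
                rec = next(parser)
            except StopIteration:
                break
            except ValueError as exc:
                raise ValueError(f"malformed record {index} in {path}: {exc}") from exc
            yield SequenceRecord(id=rec.id, seq=str(rec.seq))
            index += 1
    finally:
        handle.close()


def read_sequences(path, fmt: Optional[str] = None) -> list:
    """All records of a FASTA/FASTQ file, in file order."""
    return list(iter_sequences(path, fmt))
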