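"""Vectorised k-mer packing and hashing.

Every k-mer (k <= 64) is represented exactly by a 128-bit key split into two
uint64 words: ``hi`` holds the first min(k, 32) bases and ``lo`` the remainder,
both low-aligned with base A=0, C=1, G=2, T=3 (two bits per base). Because the
base encoding is in alphabetic order, numeric order on (hi, lo) equals
lexicographic order on equal-length k-mers, and the packing is injective, so
key equality is exact k-mer identity (no fingerprint collisions).

The 64-bit hash used for sketching is a splitmix64-style finalizer chain over
(hi, lo) keyed on (seed, k). The scalar reference implementation lives in
``seqkmer.hash_kmer``; ``hash_keys`` here is its vectorised twin and the two
are asserted bit-equal in the test suite.
"""

from __future__ import annotations

import numpy as np

MASK64 = np.uint64(0xFFFFFFFFFFFFFFFF)
_GOLDEN = 0x9E3779B97F4A7C15
_MIX1 = np.uint64(0xBF58476D1CE4E5B9)
_MIX2 = np.uint64(0x94D049BB133111EB)

MAX_K = 64

#: base -> 2-bit code; 255 marks an invalid/ambiguous character
CODE_TABLE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    CODE_TABLE[_b] = _i
    CODE_TABLE[_b + 32] = _i  # lower case
INVALID = np.uint8(255)


def encode(seq: str) -> np.ndarray:
    """Map a DNA string to uint8 codes (255 for non-ACGT characters)."""
    raw = np.frombuffer(seq.encode("latin-1"), dtype=np.uint8)
    return CODE_TABLE[raw]


def mix64(x: np.ndarray | np.uint64) -> np.ndarray | np.uint64:
    """splitmix64 finalizer (elementwise, wraps mod 2**64)."""
    x = np.uint64(x) if np.isscalar(x) else x.astype(np.uint64, copy=True)
    with np.errstate(over="ignore"):
        x = (x ^ (x >> np.uint64(30))) * _MIX1
        x = (x ^ (x >> np.uint64(27))) * _MIX2
    return x ^ (x >> np.uint64(31))


def _hash_salt(k: int, seed: int) -> np.uint64:
    a = (seed * _GOLDEN) & 0xFFFFFFFFFFFFFFFF
    b = (k * 0xFF51AFD7ED558CCD) & 0xFFFFFFFFFFFFFFFF
    return mix64(np.uint64(a ^ b))


def hash_keys(hi: np.ndarray, lo: np.ndarray, k: int, seed: int) -> np.ndarray:
    """64-bit hash of packed k-mer keys; bit-equal to seqkmer.hash_kmer."""
    salt = _hash_salt(k, seed)
    return mix64(hi.astype(np.uint64) ^ mix64(lo.astype(np.uint64) ^ salt))


class PackedSeq:
    """A code array pre-packed into 2-bit words, reusable across k values.

    Packs both orientations lazily. Word ``w`` holds bases [32w, 32w+32) with
    base j in bits [62-2*(j mod 32), 64-2*(j mod 32)) (big-endian within the
    word), plus two zero pad words so 64-bit extraction never reads past the
    end.
    """

    def __init__(self, codes: np.ndarray):
        self.codes = codes
        self.n = codes.size
        self._inv_cumsum = None
        self._words = None
        self._rc_words = None

    @property
    def inv_cumsum(self) -> np.ndarray:
        if self._inv_cumsum is None:
            cs = np.zeros(self.n + 1, dtype=np.int64)
            np.cumsum(self.codes > 3, out=cs[1:])
            self._inv_cumsum = cs
        return self._inv_cumsum

    @staticmethod
    def _pack(codes: np.ndarray) -> np.ndarray:
        n = codes.size
        nw = (n + 31) // 32
        words = np.zeros(nw + 2, dtype=np.uint64)
        clean = np.where(codes <= 3, codes, 0).astype(np.uint64)
        padded = np.zeros(nw * 32, dtype=np.uint64)
        padded[:n] = clean
        blocks = padded.reshape(nw, 32)
        for t in range(32):
            words[:nw] |= blocks[:, t] << np.uint64(62 - 2 * t)
        return words

    @property
    def words(self) -> np.ndarray:
        if self._words is None:
            self._words = self._pack(self.codes)
        return self._words

    @property
    def rc_words(self) -> np.ndarray:
        if self._rc_words is None:
            rc = np.where(self.codes <= 3, 3 - self.codes, INVALID)[::-1]
            self._rc_words = self._pack(rc)
        return self._rc_words


def _extract64(words: np.ndarray, bitpos: np.ndarray) -> np.ndarray:
    """Read 64 bits starting at each bit position (vectorised)."""
    q = bitpos >> np.uint64(6)
    s = bitpos & np.uint64(63)
    a = words[q] << s
    # (>> (64-s)) done in two steps so s == 0 shifts by 64 safely -> 0
    b = (words[q + 1] >> (np.uint64(63) - s)) >> np.uint64(1)
    return a | b


_EMPTY = np.empty(0, dtype=np.uint64)


def window_keys(ps: PackedSeq, k: int, canonical: bool):
    """Packed keys of all valid k-windows of a packed sequence.

    Windows containing any invalid code (ambiguous base or record separator)
    are dropped. Returns (hi, lo, n_skipped); in canonical mode each key is
    the lexicographic minimum of the window and its reverse complement.
    """
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}], got {k}")
    n = ps.n
    if n < k:
        return _EMPTY, _EMPTY, 0
    cs = ps.inv_cumsum
    ok = (cs[k:] - cs[:-k]) == 0
    starts = np.nonzero(ok)[0]
    n_skipped = ok.size - starts.size
    if starts.size == 0:
        return _EMPTY, _EMPTY, n_skipped

    ka = min(k, 32)
    kb = k - ka

    def keys_at(words: np.ndarray, pos: np.ndarray):
        hi = _extract64(words, (2 * pos).astype(np.uint64))
        if ka < 32:
            hi >>= np.uint64(64 - 2 * ka)
        if kb:
            lo = _extract64(words, (2 * (pos + ka)).astype(np.uint64))
            lo >>= np.uint64(64 - 2 * kb)
        else:
            lo = np.zeros_like(hi)
        return hi, lo

    hi, lo = keys_at(ps.words, starts)
    if canonical:
        rhi, rlo = keys_at(ps.rc_words, n - k - starts)
        take = (rhi < hi) | ((rhi == hi) & (rlo < lo))
        hi = np.where(take, rhi, hi)
        lo = np.where(take, rlo, lo)
    return hi, lo, n_skipped


def unique_keys(hi: np.ndarray, lo: np.ndarray):
    """Distinct (hi, lo) pairs, sorted ascending (== lexicographic order)."""
    if hi.size == 0:
        return hi, lo
    order = np.lexsort((lo, hi))
    hi, lo = hi[order], lo[order]
    keep = np.empty(hi.size, dtype=bool)
    keep[0] = True
    np.not_equal(hi[1:], hi[:-1], out=keep[1:])
    keep[1:] |= lo[1:] != lo[:-1]
    return hi[keep], lo[keep]


def merge_unique(parts_hi: list, parts_lo: list):
    """Union of several sorted-unique key arrays."""
    return unique_keys(np.concatenate(parts_hi), np.concatenate(parts_lo))


# ---------------------------------------------------------------------------
# key <-> string and key manipulation

def pack_kmer(kmer: str) -> tuple[int, int]:
    """Scalar exact packing of one k-mer into (hi, lo) Python ints."""
    k = len(kmer)
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k-mer length must be in [1, {MAX_K}], got {k}")
    codes = CODE_TABLE[np.frombuffer(kmer.encode("latin-1"), dtype=np.uint8)]
    if (codes > 3).any():
        raise ValueError(f"k-mer contains non-ACGT character: {kmer!r}")
    ka = min(k, 32)
    hi = 0
    for c in codes[:ka]:
        hi = (hi << 2) | int(c)
    lo = 0
    for c in codes[ka:]:
        lo = (lo << 2) | int(c)
    return hi, lo


_BASES = "ACGT"


def decode_key(hi: int, lo: int, k: int) -> str:
    """Inverse of pack_kmer."""
    ka = min(k, 32)
    kb = k - ka
    out = []
    v = int(hi)
    for i in range(ka):
        out.append(_BASES[(v >> (2 * (ka - 1 - i))) & 3])
    v = int(lo)
    for i in range(kb):
        out.append(_BASES[(v >> (2 * (kb - 1 - i))) & 3])
    return "".join(out)


def truncate_keys(hi: np.ndarray, lo: np.ndarray, k_from: int, k_to: int):
    """Keys of the length-k_to prefixes of length-k_from keys."""
    if k_to > k_from:
        raise ValueError("cannot truncate to a longer k")
    ka_f = min(k_from, 32)
    kb_f = k_from - ka_f
    if k_to <= ka_f:
        # prefix lives entirely in hi
        return hi >> np.uint64(2 * (ka_f - k_to)), np.zeros_like(hi)
    # k_to > 32: keep hi, take top bits of lo
    kb_t = k_to - 32
    return hi.copy(), lo >> np.uint64(2 * (kb_f - kb_t))


_M2 = np.uint64(0x3333333333333333)
_M4 = np.uint64(0x0F0F0F0F0F0F0F0F)


def _rev2_64(x: np.ndarray) -> np.ndarray:
    """Reverse the order of the 32 two-bit fields of each uint64."""
    x = ((x & _M2) << np.uint64(2)) | ((x >> np.uint64(2)) & _M2)
    x = ((x & _M4) << np.uint64(4)) | ((x >> np.uint64(4)) & _M4)
    return x.byteswap()


def revcomp_keys(hi: np.ndarray, lo: np.ndarray, k: int):
    """Packed keys of the reverse complements of length-k keys."""
    ka = min(k, 32)
    kb = k - ka
    full = np.uint64(0xFFFFFFFFFFFFFFFF)

    def mask(nchars: int) -> np.uint64:
        if nchars >= 32:
            return full
        return (np.uint64(1) << np.uint64(2 * nchars)) - np.uint64(1)

    # reversed+complemented chars, low-aligned (rev2 of a high-aligned word
    # lands the chars in the low bits; complement only within the k-mer bits)
    r_hi_part = _rev2_64(hi << np.uint64(64 - 2 * ka)) ^ mask(ka)
    if kb == 0:
        return r_hi_part, np.zeros_like(hi)
    r_lo_part = _rev2_64(lo << np.uint64(64 - 2 * kb)) ^ mask(kb)
    # rc string = reversed(lo chars) then reversed(hi chars); re-split ka/kb
    # two-step shifts keep shift counts < 64 even when kb == 32 (k == 64)
    new_hi = (r_lo_part << np.uint64(2 * (ka - kb))) | (
        (r_hi_part >> np.uint64(2 * kb - 1)) >> np.uint64(1)
    )
    if kb == 32:
        lo_mask = full
    else:
        lo_mask = (np.uint64(1) << np.uint64(2 * kb)) - np.uint64(1)
    new_lo = r_hi_part & lo_mask
    return new_hi, new_lo


def canonical_keys(hi: np.ndarray, lo: np.ndarray, k: int):
    """Elementwise min(key, revcomp key) == key of the canonical form."""
    rhi, rlo = revcomp_keys(hi, lo, k)
    take = (rhi < hi) | ((rhi == hi) & (rlo < lo))
    return np.where(take, rhi, hi), np.where(take, rlo, lo)
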