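"""Seeded generators for related microbial genomes and shotgun reads.

The community generator emulates a panel of within-genus relatives: random
ancestor genomes, each giving rise to a cluster of point-mutated descendants.
The read simulator draws fixed-length reads from chosen genomes with uniform
start positions, random strand, and i.i.d. substitution errors (no quality
model, no indels in reads) - adequate for k-mer presence/absence experiments.
All outputs are fully deterministic per seed.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator, List, Optional, Sequence, Tuple, Union

import numpy as np

from . import _kernel
from .seqkmer import SequenceRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def generate_genome(length: int, seed: int, genome_id: Optional[str] = None) -> SequenceRecord:
    """An i.i.d.-uniform random genome; deterministic per seed."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4, size=length, dtype=np.uint8)
    return SequenceRecord(id=genome_id or f"random_genome_{seed}", seq=_decode(codes))


def mutate_genome(
    parent: SequenceRecord,
    divergence: float,
    indel_rate: float = 0.0,
    seed: int = 0,
    genome_id: Optional[str] = None,
) -> SequenceRecord:
    """Point-mutated (and optionally indel-bearing) descendant of a genome.

    Each site is substituted to a uniformly chosen *different* base with
    probability ``divergence``; 1-3 bp insertions/deletions occur at
    ``indel_rate`` per site (equal odds of insertion vs deletion).
    """
    if not 0.0 <= divergence <= 1.0 or not 0.0 <= indel_rate <= 1.0:
        raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    codes = _kernel.encode(parent.seq).copy()
    sub_mask = rng.random(codes.size) < divergence
    n_sub = int(sub_mask.sum())
    if n_sub:
        shift = rng.integers(1, 4, size=n_sub, dtype=np.uint8)
        codes[sub_mask] = (codes[sub_mask] + shift) % 4
    if indel_rate > 0.0:
        positions = np.nonzero(rng.random(codes.size) < indel_rate)[0]
        if positions.size:
            is_insertion = rng.random(positions.size) < 0.5
            sizes = rng.integers(1, 4, size=positions.size)
            pieces = []
            prev = 0
            for pos, ins, sz in zip(positions, is_insertion, sizes):
                pieces.append(codes[prev:pos])
                if ins:
                    pieces.append(rng.integers(0, 4, size=int(sz), dtype=np.uint8))
                    prev = pos
                else:
                    prev = min(pos + int(sz), codes.size)
            pieces.append(codes[prev:])
            codes = np.concatenate(pieces)
    return SequenceRecord(
        id=genome_id or f"{parent.id}_mut{seed}", seq=_decode(codes)
    )


@dataclass
class CommunitySpec:
    """A panel of related genomes: clusters of descendants of shared ancestors.

    ``divergence`` may be a single per-site substitution probability or a
    (low, high) range sampled uniformly per genome; ``n_ancestors`` defaults
    to one ancestor per ~5 genomes (genus-like clusters).
    """

    n_genomes: int
    genome_length: int
    divergence: Union[float, Tuple[float, float]] = (0.01, 0.10)
    indel_rate: float = 0.0
    seed: int = 0
    n_ancestors: Optional[int] = None

    def __post_init__(self):
        lo, hi = self.divergence_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("divergence must be within [0, 1]")
        if self.n_genomes < 1 or self.genome_length < 1:
            raise ValueError("n_genomes and genome_length must be >= 1")

    @property
    def divergence_range(self) -> Tuple[float, float]:
        if isinstance(self.divergence, (tuple, list)):
            return float(self.divergence[0]), float(self.divergence[1])
        return float(self.divergence), float(self.divergence)


def generate_community(spec: CommunitySpec) -> List[SequenceRecord]:
    """Generate the genome panel described by a CommunitySpec."""
    n_anc = spec.n_ancestors or max(1, -(-spec.n_genomes // 5))
    rng = np.random.default_rng(spec.seed)
    anc_seeds = rng.integers(0, 2**31 - 1, size=n_anc)
    ancestors = [
        generate_genome(spec.genome_length, int(s), genome_id=f"ancestor_{i:03d}")
        for i, s in enumerate(anc_seeds)
    ]
    lo, hi = spec.divergence_range
    genomes = []
    for g in range(spec.n_genomes):
        anc = ancestors[g % n_anc]
        div = float(rng.uniform(lo, hi)) if hi > lo else lo
        mseed = int(rng.integers(0, 2**31 - 1))
        genomes.append(
            mutate_genome(
                anc,
                divergence=div,
                indel_rate=spec.indel_rate,
                seed=mseed,
                genome_id=f"genome_{g:03d}",
            )
        )
    return genomes


@dataclass
class ReadSimSpec:
    """Shotgun read simulation parameters (substitution-only error model)."""

    n_reads: int
    read_length: int
    substitution_error_rate: float = 0.0
    abundance_weights: Optional[Sequence[float]] = None
    seed: int = 0
    strands: str = "both"  # "both" or "forward"

    def __post_init__(self):
        if self.n_reads < 1 or self.read_length < 1:
            raise ValueError("n_reads and read_length must be >= 1")
        if not 0.0 <= self.substitution_error_rate <= 1.0:
            raise ValueError("error rate must be in [0, 1]")
        if self.strands not in ("both", "forward"):
            raise ValueError("strands must be 'both' or 'forward'")


def simulate_reads(
    genomes: Sequence[SequenceRecord],
    spec: ReadSimSpec,
    batch_size: int = 20_000,
) -> Iterator[SequenceRecord]:
    """Stream simulated reads (generator; deterministic per seed).

    Reads are drawn from genomes proportionally to ``abundance_weights``
    (uniform by default), with uniform start positions and, unless
    ``strands="forward"``, either strand with probability 1/2. Genomes shorter
    than the read length are skipped with a warning.
    """
    genomes = list(genomes)
    w = np.asarray(
        spec.abundance_weights
        if spec.abundance_weights is not None
        else np.ones(len(genomes)),
        dtype=float,
    )
    if w.size != len(genomes) or (w < 0).any() or w.sum() <= 0:
        raise ValueError("abundance weights must be non-negative and normalizable")
    too_short = np.array([len(g) < spec.read_length for g in genomes])
    if (too_short & (w > 0)).any():
        skipped = [g.id for g, t, wi in zip(genomes, too_short, w) if t and wi > 0]
        warnings.warn(f"genomes shorter than read length skipped: {skipped}")
        w = np.where(too_short, 0.0, w)
        if w.sum() <= 0:
            raise ValueError("no genome long enough for the requested read length")
    p = w / w.sum()
    codes_cache = [_kernel.encode(g.seq) if not t else None for g, t in zip(genomes, too_short)]
    rng = np.random.default_rng(spec.seed)
    L = spec.read_length
    emitted = 0
    read_no = 0
    while emitted < spec.n_reads:
        nb = min(batch_size, spec.n_reads - emitted)
        g_idx = rng.choice(len(genomes), size=nb, p=p)
        batch = np.empty((nb, L), dtype=np.uint8)
        for gi in np.unique(g_idx):
            rows = np.nonzero(g_idx == gi)[0]
            gcodes = codes_cache[gi]
            starts = rng.integers(0, gcodes.size - L + 1, size=rows.size)
            batch[rows] = gcodes[starts[:, None] + np.arange(L)]
        if spec.strands == "both":
            flip = rng.random(nb) < 0.5
            if flip.any():
                batch[flip] = 3 - batch[flip, ::-1]
        if spec.substitution_error_rate > 0.0:
            err = rng.random((nb, L)) < spec.substitution_error_rate
            n_err = int(err.sum())
            if n_err:
                shift = rng.integers(1, 4, size=n_err, dtype=np.uint8)
                batch[err] = (batch[err] + shift) % 4
        for row, gi in zip(batch, g_idx):
            yield SequenceRecord(
                id=f"read_{read_no}_{genomes[gi].id}", seq=_decode(row)
            )
            read_no += 1
        emitted += nb


# ---------------------------------------------------------------------------
# writers

def _open_write(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "wt")
    return open(path, "w")


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 80) -> None:
    with _open_write(path) as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def write_fastq(records: Iterable[SequenceRecord], path, quality_char: str = "I") -> None:
    with _open_write(path) as fh:
        for rec in records:
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{quality_char * len(rec.seq)}\n")
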