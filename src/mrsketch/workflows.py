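"""End-to-end experiment routines built from the library primitives.

These reproduce, on synthetic data generated in-process, the two standard
validation designs for truncation-based multi-resolution sketching:

* a *genus panel* sweep: pairwise Jaccard indices of closely related genomes
  across a k range, sketch estimates vs brute-force ground truth;
* a *simulated metagenome* screen: a panel of reference genomes, shotgun reads
  simulated from a member subset, and a cell-by-cell comparison of the
  truncation-based containment estimate against the classic fixed-k MinHash
  estimate.
"""

from __future__ import annotations

from typing import Dict, Sequence

import numpy as np
import pandas as pd

from . import _kernel
from .estimator import (
    _find_keys,
    screen_query,
    stream_containment,
    truncation_match_keys,
)
from .ktst import build_index
from .seqkmer import HashOrder, SequenceRecord
from .sketch import build_sketch, build_sketches_multi_k, _iter_code_chunks
from .synthdata import (
    CommunitySpec,
    ReadSimSpec,
    generate_community,
    generate_genome,
    mutate_genome,
    simulate_reads,
)

DEFAULT_KS = tuple(range(20, 61, 5))


def distinct_key_set(records: Sequence[SequenceRecord], k: int, canonical: bool = True):
    """Exact distinct (canonical) k-mer keys of records (vectorised, exact)."""
    parts_hi, parts_lo = [], []
    for chunk in _iter_code_chunks(list(records), overlap=k - 1, chunk_bases=4_000_000):
        ps = _kernel.PackedSeq(chunk)
        hi, lo, _ = _kernel.window_keys(ps, k, canonical)
        uhi, ulo = _kernel.unique_keys(hi, lo)
        parts_hi.append(uhi)
        parts_lo.append(ulo)
    if not parts_hi:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.uint64)
    return _kernel.merge_unique(parts_hi, parts_lo)


def exact_jaccard_fast(
    records_A: Sequence[SequenceRecord],
    records_B: Sequence[SequenceRecord],
    k: int,
    canonical: bool = True,
) -> float:
    """Exact J_k via packed-key set arithmetic (identical to the brute force,
    validated against it in the test suite, but scales to Mb genomes)."""
    ahi, alo = distinct_key_set(records_A, k, canonical)
    bhi, blo = distinct_key_set(records_B, k, canonical)
    if ahi.size == 0 and bhi.size == 0:
        raise ValueError("both k-mer sets empty")
    uhi, _ = _kernel.merge_unique([ahi, bhi], [alo, blo])
    n_union = uhi.size
    n_inter = ahi.size + bhi.size - n_union
    return n_inter / n_union


def genus_pair_jaccard_sweep(
    seed: int,
    n_pairs: int = 5,
    genome_length: int = 50_000,
    divergence: float = 0.02,
    ks: Sequence[int] = tuple(range(15, 61, 5)),
    kmax: int = 60,
    m: int = 1000,
) -> pd.DataFrame:
    """Ground-truth vs estimated JI for parent/descendant genome pairs.

    Returns one row per (pair, k) with columns ji_true and ji_est.
    """
    order = HashOrder(seed=seed)
    rows = []
    for p in range(n_pairs):
        parent = generate_genome(genome_length, seed * 1000 + 2 * p, genome_id=f"pair{p}_a")
        child = mutate_genome(
            parent, divergence=divergence, seed=seed * 1000 + 2 * p + 1,
            genome_id=f"pair{p}_b",
        )
        sk = build_sketch(
            [parent], kmax=kmax, m=m, order=order, canonical=True,
            dataset_id=parent.id, k_range=ks,
        )
        index = build_index([sk], k_range=ks)
        table = stream_containment(
            index, [child], engine="vector", query_cardinalities=True
        )
        for k in ks:
            rows.append(
                {
                    "pair": p,
                    "k": k,
                    "ji_true": exact_jaccard_fast([parent], [child], k, canonical=True),
                    "ji_est": float(table.cell(parent.id, k, "ji_estimate")),
                    "ci_est": float(table.cell(parent.id, k, "ci_estimate")),
                }
            )
    return pd.DataFrame(rows)


def simulated_metagenome_comparison(
    seed: int,
    n_refs: int = 100,
    genome_length: int = 500_000,
    n_members: int = 20,
    n_reads: int = 1_000_000,
    read_length: int = 150,
    error_rate: float = 0.005,
    kmax: int = 60,
    ks: Sequence[int] = DEFAULT_KS,
    m: int = 2000,
    divergence=(0.01, 0.10),
) -> Dict:
    """Truncation-based vs classic fixed-k MinHash containment on reads.

    Builds the panel, simulates reads from ``n_members`` genomes, screens the
    reads against (a) the single kmax truncation index and (b) fresh bottom-m
    sketches at every k with the same hash seed, and reports the cell-wise
    absolute CI differences. The read stream is regenerated (same seed) for
    the second pass, so memory stays bounded.
    """
    ks = sorted(set(int(k) for k in ks))
    order = HashOrder(seed=seed)
    community = generate_community(
        CommunitySpec(
            n_genomes=n_refs,
            genome_length=genome_length,
            divergence=divergence,
            seed=seed + 1,
        )
    )
    rng = np.random.default_rng(seed + 3)
    members = np.sort(rng.choice(n_refs, size=n_members, replace=False))
    weights = np.zeros(n_refs)
    weights[members] = 1.0
    read_spec = ReadSimSpec(
        n_reads=n_reads,
        read_length=read_length,
        substitution_error_rate=error_rate,
        abundance_weights=weights,
        seed=seed + 2,
    )

    # one pass per genome builds the kmax sketch and every per-k baseline
    all_ks = sorted(set(ks) | {kmax})
    per_genome = [
        build_sketches_multi_k([g], ks=all_ks, m=m, order=order,
                               canonical=True, dataset_id=g.id)
        for g in community
    ]
    index = build_index([d[kmax] for d in per_genome], k_range=ks)
    baseline_sketches = {k: [d[k] for d in per_genome] for k in ks}

    # one streaming pass serves both estimators: merge, per k, the truncated
    # index prefixes and the classic per-k sketch elements into one candidate
    # pool, then split the presence vector back out
    candidates = {}
    trunc_maps, base_maps = {}, {}
    for k in ks:
        t_keys = truncation_match_keys(index, k)
        b_keys = [baseline_sketches[k][i].element_keys() for i in range(n_refs)]
        ghi, glo = _kernel.merge_unique(
            [x[0] for x in t_keys] + [x[0] for x in b_keys],
            [x[1] for x in t_keys] + [x[1] for x in b_keys],
        )
        candidates[k] = (ghi, glo)
        trunc_maps[k] = [_find_keys(ghi, glo, h, l) for h, l in t_keys]
        base_maps[k] = [_find_keys(ghi, glo, h, l) for h, l in b_keys]
    presence, _, window_counts = screen_query(
        candidates,
        simulate_reads(community, read_spec),
        canonical=True,
        seed=order.seed,
    )
    if any(window_counts[k] == 0 for k in ks):
        raise ValueError("read set yields no valid k-mers at some k")

    rows = []
    for k in ks:
        for i, g in enumerate(community):
            c_trunc = int(presence[k][trunc_maps[k][i]].sum())
            c_base = int(presence[k][base_maps[k][i]].sum())
            m_trunc = index.sketches[i].m_effective
            m_base = baseline_sketches[k][i].m_effective
            rows.append(
                {
                    "dataset_id": g.id,
                    "k": k,
                    "ci_estimate_trunc": c_trunc / m_trunc,
                    "ci_estimate_classic": c_base / m_base,
                }
            )
    merged = pd.DataFrame(rows)
    merged["abs_ci_diff"] = (
        merged["ci_estimate_trunc"] - merged["ci_estimate_classic"]
    ).abs()
    return {
        "community": community,
        "members": [community[i].id for i in members],
        "index": index,
        "baseline_sketches": baseline_sketches,
        "cells": merged,
        "median_abs_ci_diff": float(merged["abs_ci_diff"].median()),
        "n_cells": int(len(merged)),
    }
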