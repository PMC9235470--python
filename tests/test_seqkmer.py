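"""Sequence I/O, canonicalization, enumeration and the hash order."""

import gzip

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mrsketch import _kernel
from mrsketch.seqkmer import (
    AmbiguousBaseError,
    HashOrder,
    SequenceRecord,
    canonical_form,
    enumerate_kmers,
    hash_kmer,
    read_sequences,
    reverse_complement,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=64)


class TestReadSequences:
    def test_single_record_fasta(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">g1\nAATAAG\n")
        recs = read_sequences(p)
        assert [(r.id, r.seq) for r in recs] == [("g1", "AATAAG")]

    def test_empty_fasta(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        assert read_sequences(p) == []

    def test_gzipped_fastq_discards_qualities_and_uppercases(self, tmp_path):
        p = tmp_path / "r.fastq.gz"
        with gzip.open(p, "wt") as fh:
            fh.write("@r1\nacgt\n+\nIIII\n@r2\nTTAA\n+\nIIII\n")
        recs = read_sequences(p)
        assert [(r.id, r.seq) for r in recs] == [("r1", "ACGT"), ("r2", "TTAA")]

    def test_malformed_fastq_names_record_index(self, tmp_path):
        p = tmp_path / "bad.fastq"
        p.write_text("@r1\nACGT\n+\nIIII\n@r2\nACGT\nBROKEN\n")
        with pytest.raises(ValueError, match="record 1"):
            read_sequences(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(OSError):
            read_sequences(tmp_path / "nope.fasta")


class TestCanonicalForm:
    @pytest.mark.parametrize(
        "kmer,expected",
        [("ACG", "ACG"), ("TTT", "AAA"), ("ACGT", "ACGT")],
    )
    def test_examples(self, kmer, expected):
        assert canonical_form(kmer) == expected

    def test_ambiguous_base_rejected(self):
        with pytest.raises(AmbiguousBaseError):
            canonical_form("ACN")

    @given(dna)
    def test_idempotent_and_minimal(self, kmer):
        c = canonical_form(kmer)
        assert canonical_form(c) == c
        assert c == min(kmer, reverse_complement(kmer))


class TestEnumerateKmers:
    def test_worked_example_k3(self, worked_example):
        ks = enumerate_kmers(worked_example, 3, canonical=False)
        assert ks.kmers == {"AAT", "ATA", "TAA", "AAG"}

    def test_worked_example_k2(self, worked_example):
        ks = enumerate_kmers(worked_example, 2, canonical=False)
        assert ks.kmers == {"AA", "AT", "TA", "AG"}

    def test_all_windows_hit_ambiguous_base(self):
        recs = [SequenceRecord("x", "AANTG")]
        assert enumerate_kmers(recs, 3, canonical=False).kmers == set()

    def test_k_larger_than_records(self):
        recs = [SequenceRecord("x", "ACGT")]
        assert enumerate_kmers(recs, 10, canonical=False).kmers == set()

    @given(st.text(alphabet="ACGTN", min_size=1, max_size=80), st.integers(1, 12))
    def test_canonical_set_is_canonicalized_raw_set(self, seq, k):
        recs = [SequenceRecord("x", seq)]
        raw = enumerate_kmers(recs, k, canonical=False).kmers
        canon = enumerate_kmers(recs, k, canonical=True).kmers
        assert canon == {canonical_form(x) for x in raw}
        assert len(raw) <= max(len(seq) - k + 1, 0)


class TestHashOrder:
    def test_deterministic(self, order):
        assert hash_kmer("AATAAG"[:3], order) == hash_kmer("AAT", order)

    def test_distinct_kmers_distinct_hashes(self, order):
        assert hash_kmer("AAT", order) != hash_kmer("AAG", order)

    def test_seed_changes_values(self):
        a = hash_kmer("ACGTACGT", HashOrder(seed=1))
        b = hash_kmer("ACGTACGT", HashOrder(seed=2))
        assert a != b

    def test_unique_argmin_over_worked_example(self, order):
        kmers = ["AAT", "ATA", "TAA", "AAG"]
        ranked = sorted(kmers, key=lambda x: (hash_kmer(x, order), x))
        again = sorted(kmers, key=lambda x: (hash_kmer(x, order), x))
        assert ranked == again
        assert ranked[0] in kmers

    def test_rejects_over_64mers(self, order):
        with pytest.raises(ValueError):
            hash_kmer("A" * 65, order)

    @given(st.lists(dna.filter(lambda s: len(s) == 20), min_size=2, max_size=20, unique=True))
    def test_total_order_no_ties_at_fixed_k(self, order, kmers):
        hashes = [hash_kmer(x, order) for x in kmers]
        assert len(set(hashes)) == len(kmers)


class TestKernelScalarAgreement:
    """The vectorised kernel must be bit-identical to the scalar definitions."""

    @given(st.text(alphabet="ACGTN", min_size=1, max_size=150), st.integers(1, 64))
    def test_window_keys_match_string_enumeration(self, seq, k):
        ps = _kernel.PackedSeq(_kernel.encode(seq))
        for canonical in (False, True):
            hi, lo, skipped = _kernel.window_keys(ps, k, canonical)
            got = sorted(
                _kernel.decode_key(int(h), int(l), k) for h, l in zip(hi, lo)
            )
            recs = [SequenceRecord("x", seq)]
            exp = []
            for i in range(max(len(seq) - k + 1, 0)):
                w = seq[i : i + k]
                if set(w) <= set("ACGT"):
                    exp.append(canonical_form(w) if canonical else w)
            assert got == sorted(exp)
            assert skipped == max(len(seq) - k + 1, 0) - len(exp)

    @given(dna, st.integers(0, 2**31 - 1))
    def test_vector_hash_equals_scalar_hash(self, kmer, seed):
        hi, lo = _kernel.pack_kmer(kmer)
        vec = _kernel.hash_keys(
            np.array([hi], dtype=np.uint64),
            np.array([lo], dtype=np.uint64),
            len(kmer),
            seed,
        )
        assert int(vec[0]) == hash_kmer(kmer, HashOrder(seed=seed))

    @given(dna)
    def test_revcomp_and_canonical_keys(self, kmer):
        k = len(kmer)
        hi, lo = _kernel.pack_kmer(kmer)
        hi_a = np.array([hi], dtype=np.uint64)
        lo_a = np.array([lo], dtype=np.uint64)
        rhi, rlo = _kernel.revcomp_keys(hi_a, lo_a, k)
        assert _kernel.decode_key(int(rhi[0]), int(rlo[0]), k) == reverse_complement(kmer)
        chi, clo = _kernel.canonical_keys(hi_a, lo_a, k)
        assert _kernel.decode_key(int(chi[0]), int(clo[0]), k) == canonical_form(kmer)

    @given(dna, st.data())
    def test_truncate_keys_are_prefix_keys(self, kmer, data):
        k = len(kmer)
        k_to = data.draw(st.integers(1, k))
        hi, lo = _kernel.pack_kmer(kmer)
        thi, tlo = _kernel.truncate_keys(
            np.array([hi], dtype=np.uint64), np.array([lo], dtype=np.uint64), k, k_to
        )
        assert _kernel.decode_key(int(thi[0]), int(tlo[0]), k_to) == kmer[:k_to]


def test_record_requires_id():
    with pytest.raises(ValueError):
        SequenceRecord("", "ACGT")
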