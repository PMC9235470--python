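"""Streaming containment estimation, baselines, and JI conversion."""

import numpy as np
import pytest

from mrsketch.estimator import (
    ji_from_ci,
    minhash_containment_baseline,
    minhash_jaccard_baseline,
    stream_containment,
)
from mrsketch.ktst import build_index
from mrsketch.oracle import exact_jaccard, exact_truncated_containment
from mrsketch.seqkmer import HashOrder, SequenceRecord
from mrsketch.sketch import build_sketch
from mrsketch.synthdata import ReadSimSpec, generate_genome, mutate_genome, simulate_reads


@pytest.fixture(scope="module")
def small_panel():
    """Three related references plus reads drawn from one of them."""
    order = HashOrder(seed=13)
    anc = generate_genome(8000, seed=21, genome_id="anc")
    refs = [
        mutate_genome(anc, 0.02, seed=22, genome_id="r0"),
        mutate_genome(anc, 0.05, seed=23, genome_id="r1"),
        generate_genome(8000, seed=24, genome_id="r2"),
    ]
    ks = (8, 12, 16, 20, 24)
    sketches = [
        build_sketch([g], kmax=24, m=150, order=order, dataset_id=g.id, k_range=ks)
        for g in refs
    ]
    index = build_index(sketches, k_range=ks)
    reads = list(
        simulate_reads(
            refs,
            ReadSimSpec(
                n_reads=400, read_length=100, substitution_error_rate=0.005,
                abundance_weights=[1, 0, 0], seed=25,
            ),
        )
    )
    return order, refs, index, reads, ks


class TestStreamContainment:
    def test_self_query_is_one_at_kmax(self, small_panel):
        order, refs, index, _, ks = small_panel
        table = stream_containment(index, [refs[0]], engine="vector")
        assert table.cell("r0", 24) == 1.0
        assert table.cell("r0", 24, "ji_estimate") == pytest.approx(
            ji_from_ci(1.0, index.sketches[0].cardinalities[24],
                       table.metadata["query_cardinalities"][24])
        )

    def test_disjoint_query_is_zero(self, small_panel):
        _, _, index, _, ks = small_panel
        # CC/GG-free references are unlikely; build a guaranteed-disjoint query
        q = [SequenceRecord("q", "AC" * 200)]
        table = stream_containment(index, q, engine="vector")
        sub = table.df[table.df.dataset_id == "r2"]
        # a pure AC repeat shares essentially nothing with a random genome at k>=12
        assert (table.df[table.df.k >= 12]["ci_estimate"] <= 0.02).all()

    def test_engines_agree_exactly(self, small_panel):
        _, _, index, reads, _ = small_panel
        tree = stream_containment(index, reads, engine="tree")
        vec = stream_containment(index, reads, engine="vector")
        assert (tree.df["matches"].values == vec.df["matches"].values).all()
        assert np.allclose(
            tree.df["ji_estimate"].values, vec.df["ji_estimate"].values, equal_nan=True
        )

    def test_kmax_cell_equals_classic_baseline_bit_exact(self, small_panel):
        order, refs, index, reads, _ = small_panel
        table = stream_containment(index, reads, engine="vector",
                                   query_cardinalities=False)
        for g in refs:
            classic = minhash_containment_baseline(
                [g], reads, k=24, m=150, order=order
            )
            assert table.cell(g.id, 24) == classic

    def test_full_sketch_equals_oracle_everywhere(self, genome_pair, order):
        """Saturated sketch: every CI/JI cell equals the exact truncated index."""
        parent, child = genome_pair
        ks = (8, 12, 16)
        sk = build_sketch([parent], kmax=16, m=10**9, order=order,
                          canonical=True, dataset_id="p", k_range=ks)
        index = build_index([sk], k_range=ks)
        table = stream_containment(index, [child], engine="vector")
        from mrsketch.sketch import exact_cardinality

        for k in ks:
            ci_oracle = exact_truncated_containment(
                [parent], [child], k, 16, canonical=True
            )
            assert table.cell("p", k) == pytest.approx(ci_oracle, abs=1e-12)
            ji_oracle = ji_from_ci(
                ci_oracle,
                exact_cardinality([parent], k, canonical=True),
                exact_cardinality([child], k, canonical=True),
            )
            assert table.cell("p", k, "ji_estimate") == pytest.approx(ji_oracle, abs=1e-12)

    def test_empty_query_rejected(self, small_panel):
        _, _, index, _, _ = small_panel
        with pytest.raises(ValueError):
            stream_containment(index, [SequenceRecord("q", "NNNNNNNN" * 10)])

    def test_k_outside_index_rejected(self, small_panel):
        _, _, index, reads, _ = small_panel
        with pytest.raises(ValueError):
            stream_containment(index, reads, k_range=(5,))

    def test_sampling_error_scales_binomially(self):
        """Over seeds, sd(CI at kmax) ~ sqrt(C(1-C)/m) within a factor 1.5."""
        parent = generate_genome(20000, seed=31, genome_id="p")
        child = mutate_genome(parent, 0.01, seed=32, genome_id="c")
        m, k = 150, 21
        ests = []
        for seed in range(40):
            order = HashOrder(seed=100 + seed)
            sk = build_sketch([parent], kmax=k, m=m, order=order,
                              dataset_id="p", k_range=())
            idx = build_index([sk], k_range=(k,))
            t = stream_containment(idx, [child], engine="vector",
                                   query_cardinalities=False)
            ests.append(t.cell("p", k))
        c = float(np.mean(ests))
        expected_sd = np.sqrt(c * (1 - c) / m)
        observed_sd = float(np.std(ests, ddof=1))
        assert expected_sd / 1.5 <= observed_sd <= expected_sd * 1.5


class TestBaselines:
    def test_containment_identity_and_disjoint(self, order):
        a = generate_genome(3000, seed=41, genome_id="a")
        b = generate_genome(3000, seed=42, genome_id="b")
        assert minhash_containment_baseline([a], [a], k=21, m=100, order=order) == 1.0
        assert minhash_containment_baseline([a], [b], k=21, m=100, order=order) == 0.0

    def test_jaccard_identity_and_disjoint(self, order):
        a = generate_genome(3000, seed=43, genome_id="a")
        b = generate_genome(3000, seed=44, genome_id="b")
        assert minhash_jaccard_baseline([a], [a], k=21, m=100, order=order) == 1.0
        assert minhash_jaccard_baseline([a], [b], k=21, m=100, order=order) == 0.0

    def test_jaccard_unbiased_over_seeds(self):
        """Mean over seeds within 3*sqrt(J(1-J)/m) of the exact J."""
        a = generate_genome(2000, seed=45, genome_id="a")
        b = mutate_genome(a, 0.02, seed=46, genome_id="b")
        k, m = 12, 100
        j_exact = exact_jaccard([a], [b], k)
        ests = [
            minhash_jaccard_baseline([a], [b], k, m, HashOrder(seed=s))
            for s in range(220)
        ]
        tol = 3 * np.sqrt(j_exact * (1 - j_exact) / m) / np.sqrt(len(ests))
        # the bound in the claim is per-estimate; the mean is tighter still
        assert abs(np.mean(ests) - j_exact) <= 3 * np.sqrt(j_exact * (1 - j_exact) / m)
        assert abs(np.mean(ests) - j_exact) <= 4 * tol


class TestJiFromCi:
    @pytest.mark.parametrize(
        "ci,ca,cb,expected",
        [(1.0, 500, 500, 1.0), (0.0, 10, 10, 0.0), (0.5, 100, 300, 50 / 350)],
    )
    def test_examples(self, ci, ca, cb, expected):
        assert ji_from_ci(ci, ca, cb) == pytest.approx(expected)

    def test_zero_cardinality_rejected(self):
        with pytest.raises(ValueError):
            ji_from_ci(0.5, 0, 10)

    def test_monotone_in_ci(self):
        vals = [ji_from_ci(c, 120, 480) for c in np.linspace(0, 1, 21)]
        assert all(x <= y for x, y in zip(vals, vals[1:]))
        assert all(0.0 <= v <= 1.0 for v in vals)


class TestCsvOutput:
    def test_header_and_rounding(self, small_panel, tmp_path):
        _, _, index, reads, _ = small_panel
        table = stream_containment(index, reads, engine="vector")
        out = tmp_path / "t.csv"
        table.to_csv(out)
        lines = out.read_text().splitlines()
        assert lines[0] == "dataset_id,k,ci_estimate,ji_estimate,matches,sketch_size"
        assert len(lines) == 1 + len(table.df)
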