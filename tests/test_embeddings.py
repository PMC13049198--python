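"""Domain/architecture embeddings against brute-force oracles and hand values."""

import math

import numpy as np
import pytest

from archsem.corpus_io import DomainArchitecture, corpus_from_architectures
from archsem.embeddings import (
    architecture_embedding,
    parse_embedding_id,
    pmi_embedding,
    read_embedding_tsv,
    skipgram_embedding,
    tfidf_embedding,
    write_embedding_tsv,
)


def _corpus(*seqs):
    return corpus_from_architectures(
        DomainArchitecture(tuple(s), frozenset({f"p{i}"})) for i, s in enumerate(seqs)
    )


def _pmi_oracle(corpus, psi):
    """Independent recount: dict-of-dicts PMI from first principles."""
    vocab = sorted(corpus.vocabulary)
    uni_total = sum(corpus.unigram_counts.values())
    p = {d: corpus.unigram_counts[d] / uni_total for d in vocab}
    joint_total = sum(corpus.bigram_counts.values()) + psi * len(vocab) ** 2
    out = {}
    for a in vocab:
        for b in vocab:
            pj = (corpus.bigram_counts.get((a, b), 0) + psi) / joint_total
            out[(a, b)] = (
                math.log2(pj / (p[a] * p[b])) if pj > 0 else -math.inf
            )
    return out


class TestPMI:
    def test_hand_value_without_pseudocount(self):
        corpus = _corpus("AB", "AC")
        emb = pmi_embedding(corpus, pseudocount=0.0)
        i = {d: k for k, d in enumerate(emb.vocab)}
        # P(A,B)=1/2, P(A)=1/2, P(B)=1/4 → log2(4) = 2
        assert emb.matrix[i["A"], i["B"]] == pytest.approx(2.0, abs=1e-12)

    def test_hand_value_with_default_pseudocount(self):
        corpus = _corpus("AB", "AC")
        emb = pmi_embedding(corpus, pseudocount=0.0009)
        i = {d: k for k, d in enumerate(emb.vocab)}
        # joint total 2 + 9ψ; P(A,B) = 1.0009/2.0081
        assert emb.matrix[i["A"], i["B"]] == pytest.approx(1.9955, abs=1e-4)

    def test_pair_at_independence_rate_scores_zero(self):
        corpus = _corpus("AB", "BA", "AA", "BB")
        emb = pmi_embedding(corpus, pseudocount=0.0)
        i = {d: k for k, d in enumerate(emb.vocab)}
        # every ordered pair has joint 1/4 = P(A)P(B)
        assert emb.matrix[i["A"], i["B"]] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("psi", [0.0, 0.0009, 0.5])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle_on_small_corpora(self, psi, seed):
        rng = np.random.default_rng(seed)
        seqs = [
            [str(d) for d in rng.integers(0, 6, size=rng.integers(1, 6))]
            for _ in range(rng.integers(3, 15))
        ]
        corpus = corpus_from_architectures(
            DomainArchitecture(tuple(s), frozenset({f"p{i}"})) for i, s in enumerate(seqs)
        )
        if not corpus.bigram_counts:
            return
        emb = pmi_embedding(corpus, pseudocount=psi)
        oracle = _pmi_oracle(corpus, psi)
        i = {d: k for k, d in enumerate(emb.vocab)}
        for (a, b), v in oracle.items():
            got = emb.matrix[i[a], i[b]]
            if math.isinf(v):
                assert math.isinf(got) and got < 0
            else:
                assert got == pytest.approx(v, abs=1e-9)

    def test_all_ordered_pairs_mode_counts_nonadjacent(self):
        corpus = _corpus("ABC")
        emb = pmi_embedding(corpus, pseudocount=0.0, pairs="all_ordered")
        i = {d: k for k, d in enumerate(emb.vocab)}
        assert np.isfinite(emb.matrix[i["A"], i["C"]])  # (A,C) counted

    def test_zero_bigram_corpus_rejected(self):
        with pytest.raises(ValueError):
            pmi_embedding(_corpus("A", "B"))


class TestTFIDF:
    def test_hand_values_without_log(self):
        corpus = _corpus("XXY", "YZ", "Z")
        emb = tfidf_embedding(corpus)
        i = {d: k for k, d in enumerate(emb.vocab)}
        cols = {k: j for j, k in enumerate(a.domains for a in corpus.architectures)}
        x = emb.matrix[i["X"]]
        assert x[cols[("X", "X", "Y")]] == pytest.approx(6.0)  # tf 2 × idf 3/1
        assert x[cols[("Y", "Z")]] == 0.0
        y = emb.matrix[i["Y"]]
        assert y[cols[("X", "X", "Y")]] == pytest.approx(1.5)  # tf 1 × idf 3/2
        assert y[cols[("Y", "Z")]] == pytest.approx(1.5)

    def test_ubiquitous_domain_has_unit_components(self):
        corpus = _corpus("AX", "AY", "AZ")
        emb = tfidf_embedding(corpus)
        i = {d: k for k, d in enumerate(emb.vocab)}
        assert np.allclose(emb.matrix[i["A"]], 1.0)

    def test_sparsity_nonzero_iff_domain_occurs(self, synth):
        _, corpus, _, _, _ = synth
        emb = tfidf_embedding(corpus)
        i = {d: k for k, d in enumerate(emb.vocab)}
        for j, arch in enumerate(corpus.architectures[:50]):
            present = set(arch.domains)
            col = emb.matrix[:, j]
            for d in emb.vocab[:40]:
                assert (col[i[d]] != 0) == (d in present)

    def test_dimension_is_corpus_size(self):
        corpus = _corpus("AB", "CD", "E")
        assert tfidf_embedding(corpus).dim == 3


class TestSkipgram:
    def test_same_seed_is_bitwise_identical(self):
        corpus = _corpus("ABCD", "BCA", "DAB")
        e1 = skipgram_embedding(corpus, m=4, window=2, epochs=3, seed=5)
        e2 = skipgram_embedding(corpus, m=4, window=2, epochs=3, seed=5)
        assert np.array_equal(e1.matrix, e2.matrix)

    def test_matrix_shape_is_vocab_by_m(self):
        corpus = _corpus("ABCD", "BCA")
        emb = skipgram_embedding(corpus, m=7, window=1, epochs=1, seed=0)
        assert emb.matrix.shape == (4, 7)

    def test_every_domain_gets_a_vector_even_singletons(self):
        corpus = _corpus("AB", "Q")  # Q occurs once, in a length-1 DA
        emb = skipgram_embedding(corpus, m=3, window=1, epochs=1, seed=0)
        assert "Q" in emb

    def test_invalid_dimensions_fatal(self):
        corpus = _corpus("AB")
        with pytest.raises(ValueError):
            skipgram_embedding(corpus, m=0, window=1)
        with pytest.raises(ValueError):
            skipgram_embedding(corpus, m=5, window=0)

    def test_synonyms_closer_than_random_pairs(self, synth):
        _, corpus, truth, _, _ = synth
        emb = skipgram_embedding(corpus, m=10, window=1, seed=2)

        def cos(a, b):
            va, vb = emb.vector(a), emb.vector(b)
            return float(va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb)))

        used = [sorted(g) for g in truth.synonym_groups if all(d in corpus.vocabulary for d in g)]
        assert used, "fixture must instantiate at least one synonym group"
        syn = np.median([cos(g[0], g[1]) for g in used])
        rng = np.random.default_rng(0)
        vocab = sorted(corpus.vocabulary)
        rand = np.median(
            [cos(*rng.choice(vocab, size=2, replace=False)) for _ in range(100)]
        )
        assert syn > rand


class TestArchitectureEmbedding:
    def test_length_one_da_is_identity(self):
        corpus = _corpus("A")
        emb = tfidf_embedding(corpus)
        arch = architecture_embedding(corpus, emb)
        assert np.allclose(arch.vector(("A",)), emb.vector("A"))

    def test_mean_with_multiplicity(self):
        corpus = _corpus("AAB")
        emb = tfidf_embedding(corpus)
        arch = architecture_embedding(corpus, emb)
        expected = (2 * emb.vector("A") + emb.vector("B")) / 3
        assert np.allclose(arch.vector(("A", "A", "B")), expected)

    def test_order_invariance(self):
        c1, c2 = _corpus("ABC", "CBA"), _corpus("ABC", "CBA")
        emb = pmi_embedding(c1)
        arch = architecture_embedding(c2, emb)
        assert np.allclose(arch.vector(("A", "B", "C")), arch.vector(("C", "B", "A")))

    def test_linearity_under_scaling(self):
        corpus = _corpus("AB", "BC")
        emb = tfidf_embedding(corpus)
        arch1 = architecture_embedding(corpus, emb)
        emb.matrix *= 3.0
        arch2 = architecture_embedding(corpus, emb)
        assert np.allclose(arch2.matrix, 3.0 * arch1.matrix)

    def test_unknown_domain_is_fatal(self):
        small, big = _corpus("AB"), _corpus("AB", "CD")
        emb = tfidf_embedding(small)
        with pytest.raises(ValueError):
            architecture_embedding(big, emb)


class TestPlumbing:
    @pytest.mark.parametrize(
        "name,expect",
        [
            ("tfidf", {"kind": "tfidf"}),
            ("pmi", {"kind": "pmi"}),
            ("w2v(10,5)", {"kind": "w2v", "m": 10, "w": 5}),
            ("w2v:5,1", {"kind": "w2v", "m": 5, "w": 1}),
        ],
    )
    def test_embedding_id_parsing(self, name, expect):
        assert parse_embedding_id(name) == expect

    def test_embedding_tsv_round_trip(self, tmp_path):
        corpus = _corpus("AB", "AC")
        emb = pmi_embedding(corpus)
        write_embedding_tsv(emb, tmp_path / "pmi.tsv")
        back = read_embedding_tsv(tmp_path / "pmi.tsv")
        assert back.vocab == emb.vocab
        assert np.allclose(back.matrix, emb.matrix)
        assert back.params["psi"] == emb.params["psi"]
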