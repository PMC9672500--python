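"""Concept enrichment, projection, autoencoders and the attention block."""

import numpy as np
import pytest

from hiercode.representation import (AttentiveEncoder, ConceptLexicon,
                                     ConceptVectorizer, DenoisingEncoder,
                                     RankError, VarianceProjection,
                                     attention_block, enrich_to_concepts,
                                     enumerate_true_paths,
                                     pooled_training_count)

from conftest import build_tree


@pytest.fixture
def lexicon():
    return ConceptLexicon(
        {"naht": "c1", "riss": "c2", "geburt": "c3"},
        {"c1": [("c4", 0.5)], "c2": [("c4", 0.25), ("c5", 1.0)]})


class TestEnrichToConcepts:
    def test_empty_text_is_zero_vector(self, lexicon):
        assert enrich_to_concepts("", lexicon) == {}

    def test_single_term_with_similar_concept(self, lexicon):
        assert enrich_to_concepts("naht", lexicon) == {"c1": 1.0, "c4": 0.5}

    def test_contributions_accumulate(self, lexicon):
        out = enrich_to_concepts("naht riss", lexicon)
        assert out == {"c1": 1.0, "c2": 1.0, "c4": 0.75, "c5": 1.0}

    def test_unknown_tokens_ignored(self, lexicon):
        assert enrich_to_concepts("xyz abc", lexicon) == {}

    def test_order_invariant(self, lexicon):
        a = enrich_to_concepts("naht riss geburt", lexicon)
        b = enrich_to_concepts("geburt naht riss", lexicon)
        assert a == b

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_accumulation(self, seed):
        rng = np.random.default_rng(seed)
        terms = [f"t{i}" for i in range(10)]
        concepts = [f"c{i}" for i in range(6)]
        t2c = {t: concepts[int(rng.integers(6))] for t in terms}
        sim = {c: [(concepts[int(rng.integers(6))],
                    float(rng.uniform(0.1, 1.0)))]
               for c in concepts if rng.random() < 0.5}
        lex = ConceptLexicon(t2c, sim)
        toks = [terms[int(rng.integers(10))] for _ in range(6)]
        expected: dict[str, float] = {}
        for tok in toks:
            c = t2c[tok]
            expected[c] = expected.get(c, 0) + 1.0
            for s, w in sim.get(c, []):
                expected[s] = expected.get(s, 0) + w
        got = enrich_to_concepts(" ".join(toks), lex)
        assert set(got) == set(expected)
        for k in got:
            assert got[k] == pytest.approx(expected[k])

    def test_vectorizer_round_trip(self, lexicon, tmp_path):
        lexicon.to_tsv(tmp_path / "lex.tsv")
        lex2 = ConceptLexicon.from_tsv(tmp_path / "lex.tsv")
        v1 = ConceptVectorizer(lexicon).fit().transform(["naht riss"])
        v2 = ConceptVectorizer(lex2).fit().transform(["naht riss"])
        assert (v1 != v2).nnz == 0


class TestVarianceProjection:
    def test_lossless_at_intrinsic_dimension(self, rng):
        X = rng.normal(size=(30, 4))
        proj = VarianceProjection(4).fit(X)
        R = proj.inverse_transform(proj.transform(X))
        assert np.max(np.abs(R - X)) < 1e-8

    def test_planted_two_dim_subspace_recovered(self, rng):
        basis = rng.normal(size=(2, 5))
        X = rng.normal(size=(40, 2)) @ basis + rng.normal(size=5)
        proj = VarianceProjection(2).fit(X)
        R = proj.inverse_transform(proj.transform(X))
        assert np.max(np.abs(R - X)) < 1e-8

    def test_variance_ranking_non_increasing(self, rng):
        X = rng.normal(size=(50, 6)) * np.array([5, 4, 3, 2, 1, 0.5])
        proj = VarianceProjection(5).fit(X)
        assert np.all(np.diff(proj.explained_variance_) <= 1e-12)

    def test_basis_orthonormal(self, rng):
        proj = VarianceProjection(3).fit(rng.normal(size=(30, 6)))
        G = proj.components_ @ proj.components_.T
        np.testing.assert_allclose(G, np.eye(3), atol=1e-10)

    def test_degenerate_input_raises_rank_error(self):
        X = np.ones((10, 4))
        with pytest.raises(RankError):
            VarianceProjection(2).fit(X)

    def test_sign_convention_deterministic(self, rng):
        X = rng.normal(size=(25, 5))
        a = VarianceProjection(3).fit(X).components_
        b = VarianceProjection(3).fit(X).components_
        np.testing.assert_array_equal(a, b)
        idx = np.argmax(np.abs(a), axis=1)
        assert np.all(a[np.arange(3), idx] > 0)


class TestDenoisingEncoder:
    def test_training_reduces_reconstruction_loss(self, rng):
        X = rng.normal(size=(60, 10))
        enc = DenoisingEncoder(layer_sizes=(8, 4), corruption=0.0,
                               epochs=40, random_state=0)
        enc.fit(X)
        for log in enc.loss_log_:
            assert log[-1] < log[0]

    def test_output_dimension_matches_last_layer(self, rng):
        X = rng.normal(size=(20, 12))
        enc = DenoisingEncoder(layer_sizes=(6, 3), epochs=2,
                               random_state=0).fit(X)
        assert enc.transform(X).shape == (20, 3)

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(30, 8))
        a = DenoisingEncoder((5,), epochs=3, random_state=7).fit(X)
        b = DenoisingEncoder((5,), epochs=3, random_state=7).fit(X)
        np.testing.assert_array_equal(a.transform(X), b.transform(X))

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            DenoisingEncoder((4,)).fit(np.empty((0, 5)))

    def test_encoding_beats_random_linear_map_on_clusters(self):
        """Cluster structure survives encoding better than a random map
        of equal dimension (majority over 5 seeds)."""
        from sklearn.metrics import silhouette_score

        wins = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            centers = rng.normal(0, 4, size=(3, 12))
            X = np.vstack([c + rng.normal(0, 0.7, size=(25, 12))
                           for c in centers])
            labels = np.repeat([0, 1, 2], 25)
            enc = DenoisingEncoder(layer_sizes=(4,), corruption=0.05,
                                   epochs=300, lr=1e-2, batch_size=16,
                                   random_state=seed).fit(X)
            s_enc = silhouette_score(enc.transform(X), labels)
            s_rand = silhouette_score(
                X @ rng.normal(size=(12, 4)), labels)
            wins += s_enc >= s_rand
        assert wins >= 3


class TestAttentionBlock:
    def test_single_position_gets_full_softmax_weight(self):
        enc = AttentiveEncoder(d_m=4, n_heads=2, random_state=0)
        W = enc.attention_weights(np.ones((1, 4)))
        np.testing.assert_allclose(W, np.ones((2, 1, 1)))

    def test_identical_rows_give_uniform_attention(self):
        enc = AttentiveEncoder(d_m=4, n_heads=2, random_state=0)
        X = np.tile([0.3, -1.2, 0.5, 2.0], (5, 1))
        W = enc.attention_weights(X)
        np.testing.assert_allclose(W, np.full((2, 5, 5), 0.2), atol=1e-12)

    def test_attention_rows_are_distributions(self, rng):
        enc = AttentiveEncoder(d_m=8, n_heads=4, random_state=1)
        W = enc.attention_weights(rng.normal(size=(6, 8)))
        assert np.all(W >= 0)
        np.testing.assert_allclose(W.sum(axis=-1), np.ones((4, 6)))

    def test_matches_hand_matrix_computation(self):
        """2-token, single-head case against independent matrix arithmetic."""
        enc = AttentiveEncoder(d_m=2, n_heads=1, d_f=3, random_state=0)
        enc.W_q = np.array([[1.0, 0.0], [0.0, 1.0]])
        enc.W_k = np.array([[0.5, 0.0], [0.0, 0.5]])
        enc.W_v = np.array([[1.0, 1.0], [0.0, 1.0]])
        enc.W_1 = np.array([[1.0, 0.0, 0.5], [0.0, 1.0, -0.5]])
        enc.b_1 = np.array([0.1, -0.1, 0.0])
        enc.W_2 = np.array([[1.0, 0.0], [0.5, 0.5], [0.0, 1.0]])
        enc.b_2 = np.array([0.0, 0.2])
        X = np.array([[1.0, 0.0], [0.0, 2.0]])

        # independent recomputation with raw numpy
        Q, K, V = X @ enc.W_q, X @ enc.W_k, X @ enc.W_v
        S = Q @ K.T / np.sqrt(2)
        P = np.exp(S - S.max(1, keepdims=True))
        P /= P.sum(1, keepdims=True)
        A = P @ V
        r1 = A + X
        a = (r1 - r1.mean(1, keepdims=True)) / np.sqrt(
            r1.var(1, keepdims=True) + 1e-6)
        f = np.maximum(a @ enc.W_1 + enc.b_1, 0) @ enc.W_2 + enc.b_2
        r2 = f + a
        expected = (r2 - r2.mean(1, keepdims=True)) / np.sqrt(
            r2.var(1, keepdims=True) + 1e-6)

        np.testing.assert_allclose(attention_block(X, enc), expected,
                                   atol=1e-10)

    def test_shape_mismatch_rejected(self, rng):
        enc = AttentiveEncoder(d_m=4, n_heads=2, random_state=0)
        with pytest.raises(ValueError):
            enc.forward(rng.normal(size=(3, 5)))

    def test_inference_is_pure(self, rng):
        enc = AttentiveEncoder(d_m=4, n_heads=2, random_state=3)
        X = rng.normal(size=(4, 4))
        np.testing.assert_array_equal(enc.forward(X), enc.forward(X))

    def test_backward_matches_finite_differences(self, rng):
        """Analytic gradients of a scalar loss agree with central
        differences for every parameter matrix."""
        enc = AttentiveEncoder(d_m=4, n_heads=2, d_f=6, random_state=5)
        X = rng.normal(size=(3, 4))
        T = rng.normal(size=(3, 4))

        def loss():
            H = enc.forward(X)
            return float(np.sum((H - T) ** 2))

        H, cache = enc.forward(X, cache=True)
        grads, gX = enc.backward(2.0 * (H - T), cache)
        eps = 1e-6
        for P, G in zip(enc.params(), grads):
            flat = P.reshape(-1)
            for idx in rng.choice(flat.size, size=min(6, flat.size),
                                  replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss()
                flat[idx] = orig - eps
                down = loss()
                flat[idx] = orig
                num = (up - down) / (2 * eps)
                assert G.reshape(-1)[idx] == pytest.approx(num, abs=1e-4)
        # input gradient too
        for idx in rng.choice(X.size, size=4, replace=False):
            flat = X.reshape(-1)
            orig = flat[idx]
            flat[idx] = orig + eps
            up = loss()
            flat[idx] = orig - eps
            down = loss()
            flat[idx] = orig
            assert gX.reshape(-1)[idx] == pytest.approx(
                (up - down) / (2 * eps), abs=1e-4)


class TestTruePathEncoders:
    def test_pooled_count_sums_per_node_positives(self):
        """A three-node path with 910, 681 and 131 positives pools 1,722
        training examples for its path-level encoder."""
        from hiercode.corpus import NodeTrainingSet

        sets = {
            "75": NodeTrainingSet("75", [f"a{i}" for i in range(910)]),
            "75.5": NodeTrainingSet("75.5", [f"b{i}" for i in range(681)]),
            "75.51": NodeTrainingSet("75.51", [f"c{i}" for i in range(131)]),
        }
        assert pooled_training_count(sets, ["75", "75.5", "75.51"]) == 1722

    def test_path_enumeration_matches_brute_force(self, rng):
        h = build_tree([("A.1", "A"), ("A.2", "A"), ("A.1.1", "A.1"),
                        ("B.1", "B")], ["A", "B"])
        trainable = {"A", "A.1", "A.1.1", "B.1"}
        paths = enumerate_true_paths(h, trainable)
        assert set(paths) == trainable
        assert paths["A.1.1"] == ["A", "A.1", "A.1.1"]
        assert paths["B.1"] == ["B", "B.1"]

    def test_single_node_path_pools_own_positives(self):
        from hiercode.corpus import NodeTrainingSet

        sets = {"A": NodeTrainingSet("A", ["q1", "q2"])}
        assert pooled_training_count(sets, ["A"]) == 2

    def test_training_produces_encoder_per_path_and_is_pure(self, rng):
        from hiercode.corpus import NodeTrainingSet
        from hiercode.representation import fit_true_path_attentive_encoders

        h = build_tree([("A.1", "A")], ["A"])
        vocab = {f"w{i}": i for i in range(6)}
        sets = {"A": NodeTrainingSet("A", ["w0 w1", "w2 w0"], ["w4 w5"]),
                "A.1": NodeTrainingSet("A.1", ["w0 w3"], ["w5"])}
        paths = enumerate_true_paths(h, {"A", "A.1"})
        models = fit_true_path_attentive_encoders(
            sets, h, paths, vocab=vocab, d_m=4, n_heads=2,
            pretrain_epochs=2, finetune_epochs=2, seed=0)
        assert set(models) == {"A", "A.1"}
        m = models["A.1"]
        v1 = m.encode([0, 3])
        v2 = m.encode([0, 3])
        np.testing.assert_array_equal(v1, v2)
        assert 0.0 <= m.match_probability([0, 3]) <= 1.0
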