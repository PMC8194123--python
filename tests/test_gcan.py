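"""Graph-convolution and autoencoder-embedding behaviour."""

import numpy as np
import pytest

from gcanddi.chem import SimilarityGraph, build_similarity_graph
from gcanddi.gcan import AutoencoderEmbedder, GCANEmbedder, graph_conv_layer
from gcanddi.simulate import SimulationConfig, simulate_drugs


def brute_force_aggregation(W, X, theta, bias):
    """Two-loop reference for one linear graph-convolution layer."""
    n, dout = X.shape[0], theta.shape[1]
    out = np.zeros((n, dout))
    mixed = np.zeros_like(X)
    for i in range(n):
        for j in range(n):
            mixed[i] += W[i, j] * X[j]
    for i in range(n):
        out[i] = mixed[i] @ theta + bias
    return out


class TestGraphConvLayer:
    def test_identity_graph_identity_theta_is_elementwise_tanh(self, rng):
        X = rng.standard_normal((4, 3))
        out = graph_conv_layer(np.eye(4), X, np.eye(3), 0.0, "tanh")
        np.testing.assert_allclose(out, np.tanh(X), atol=1e-12)

    def test_three_node_toy_graph_equals_neighbor_average(self):
        W = np.array([[0.5, 0.5, 0.0], [0.0, 0.2, 0.8], [1 / 3, 1 / 3, 1 / 3]])
        X = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        out = graph_conv_layer(W, X, np.eye(2), 0.0, "linear")
        np.testing.assert_allclose(out, brute_force_aggregation(W, X, np.eye(2), 0.0),
                                   atol=1e-12)

    def test_uniform_features_are_fixed_point_of_row_stochastic_mixing(self, rng):
        row = rng.standard_normal(5)
        X = np.tile(row, (6, 1))
        W = rng.random((6, 6))
        W /= W.sum(axis=1, keepdims=True)
        out = graph_conv_layer(W, X, np.eye(5), 0.0, "linear")
        np.testing.assert_allclose(out, X, atol=1e-12)

    def test_matches_double_loop_oracle_on_random_instances(self, rng):
        for _ in range(25):
            n = int(rng.integers(2, 9))
            d = int(rng.integers(1, 6))
            dout = int(rng.integers(1, 6))
            W = rng.random((n, n))
            X = rng.standard_normal((n, d))
            theta = rng.standard_normal((d, dout))
            bias = rng.standard_normal(dout)
            for act, fn in (("linear", lambda z: z), ("tanh", np.tanh)):
                got = graph_conv_layer(W, X, theta, bias, act)
                want = fn(brute_force_aggregation(W, X, theta, bias))
                np.testing.assert_allclose(got, want, atol=1e-6)

    def test_dimension_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            graph_conv_layer(np.eye(3), rng.standard_normal((3, 4)),
                             rng.standard_normal((5, 2)))
        with pytest.raises(ValueError):
            graph_conv_layer(np.eye(2), rng.standard_normal((3, 4)),
                             rng.standard_normal((4, 2)))


@pytest.fixture(scope="module")
def trained_gcan():
    config = SimulationConfig(n_drugs=30, n_classes=3, bit_flip_rate=0.0,
                              expr_noise_sd=0.0, seed=21)
    drugs = simulate_drugs(config)
    graph = build_similarity_graph(drugs.fingerprints, drug_ids=drugs.ids, k=40)
    model = GCANEmbedder(epochs=1000, early_stopping=False, random_state=3)
    model.fit(drugs.signatures, drugs.fingerprints, graph=graph)
    return drugs, graph, model


class TestGcanTraining:
    def test_loss_decreases(self, trained_gcan):
        _, _, model = trained_gcan
        assert model.loss_trace_[-1] < model.loss_trace_[0]
        assert np.isfinite(model.loss_trace_).all()

    def test_same_seed_reproduces_loss_trace(self, small_cohort):
        _, drugs, _ = small_cohort
        graph = build_similarity_graph(drugs.fingerprints, drug_ids=drugs.ids, k=10)
        kw = dict(epochs=40, early_stopping=False, random_state=7)
        a = GCANEmbedder(**kw).fit(drugs.signatures, drugs.fingerprints, graph=graph)
        b = GCANEmbedder(**kw).fit(drugs.signatures, drugs.fingerprints, graph=graph)
        np.testing.assert_array_equal(a.loss_trace_, b.loss_trace_)
        np.testing.assert_array_equal(a.embedding_, b.embedding_)

    def test_noiseless_reconstruction_accuracy(self, trained_gcan):
        drugs, graph, model = trained_gcan
        acc = model.reconstruction_accuracy(drugs.signatures, drugs.fingerprints)
        assert acc > 0.95

    def test_embedding_is_deterministic_and_class_structured(self, trained_gcan):
        drugs, graph, model = trained_gcan
        e1 = model.transform(drugs.signatures)
        e2 = model.transform(drugs.signatures)
        np.testing.assert_array_equal(e1, e2)
        assert e1.shape == (len(drugs), 512)
        # brute-force pairwise cosine: within-class exceeds between-class
        norm = e1 / np.linalg.norm(e1, axis=1, keepdims=True)
        cos = norm @ norm.T
        within, between = [], []
        for i in range(len(drugs)):
            for j in range(i + 1, len(drugs)):
                (within if drugs.classes[i] == drugs.classes[j] else between).append(cos[i, j])
        assert np.mean(within) > np.mean(between)

    def test_identical_rows_embed_identically(self, rng):
        X = rng.standard_normal((6, 20))
        X[3] = X[0]
        Y = (rng.random((6, 32)) < 0.5).astype(float)
        Y[3] = Y[0]
        # identity graph and identical inputs/graph rows for drugs 0 and 3
        model = GCANEmbedder(hidden_dim=16, embed_dim=8, epochs=30,
                             early_stopping=False, random_state=0)
        model.fit(X, Y, graph=None)
        emb = model.transform(X)
        np.testing.assert_allclose(emb[0], emb[3], atol=1e-12)

    def test_identity_graph_reproduces_autoencoder_baseline(self, small_cohort):
        _, drugs, _ = small_cohort
        kw = dict(hidden_dim=32, embed_dim=16, epochs=30, early_stopping=False,
                  random_state=5)
        gcan = GCANEmbedder(**kw).fit(drugs.signatures, drugs.fingerprints,
                                      graph=np.eye(len(drugs)))
        auto = AutoencoderEmbedder(**kw).fit(drugs.signatures, drugs.fingerprints)
        np.testing.assert_array_equal(gcan.loss_trace_, auto.loss_trace_)
        np.testing.assert_array_equal(gcan.embedding_, auto.embedding_)

    def test_l2_off_never_increases_final_loss(self, small_cohort):
        _, drugs, _ = small_cohort
        kw = dict(hidden_dim=32, embed_dim=16, epochs=60, early_stopping=False,
                  dropout=0.0, random_state=2)
        with_l2 = GCANEmbedder(l2_rate=1e-5, **kw).fit(drugs.signatures, drugs.fingerprints)
        without = GCANEmbedder(l2_rate=0.0, **kw).fit(drugs.signatures, drugs.fingerprints)
        assert without.loss_trace_[-1] <= with_l2.loss_trace_[-1] + 1e-9

    def test_mismatched_graph_is_a_contract_error(self, small_cohort):
        _, drugs, _ = small_cohort
        with pytest.raises(ValueError):
            GCANEmbedder(epochs=1).fit(drugs.signatures, drugs.fingerprints,
                                       graph=np.eye(len(drugs) + 1))

    def test_checkpoint_round_trip_preserves_embeddings(self, trained_gcan, tmp_path):
        drugs, _, model = trained_gcan
        model.save(tmp_path / "ckpt")
        again = GCANEmbedder.load(tmp_path / "ckpt")
        np.testing.assert_array_equal(again.transform(drugs.signatures),
                                      model.transform(drugs.signatures))
        np.testing.assert_array_equal(again.loss_trace_, model.loss_trace_)

    def test_embedding_respects_hidden_activation_range(self, trained_gcan):
        _, _, model = trained_gcan
        emb = model.embedding_
        assert np.isfinite(emb).all()
        assert (np.abs(emb) <= 1.0).all()
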