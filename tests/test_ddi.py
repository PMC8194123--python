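"""Sequence-LSTM and concatenation-DNN classifier contracts."""

import numpy as np
import pytest

from gcanddi.ddi import (
    DNNDdiClassifier,
    LSTMDdiClassifier,
    make_pair_sequence,
    pair_design_matrix,
)
from gcanddi.gcan import EmbeddedFeatures


@pytest.fixture
def toy_features():
    mat = np.array([[1.0, 0.0], [0.0, 1.0], [2.0, 2.0]])
    return EmbeddedFeatures(["d1", "d2", "d3"], mat, kind="original")


class TestPairSequences:
    def test_sequence_order_follows_pair_order(self, toy_features):
        seq = make_pair_sequence(toy_features, ("d1", "d2"))
        np.testing.assert_array_equal(seq, [[1.0, 0.0], [0.0, 1.0]])
        rev = make_pair_sequence(toy_features, ("d2", "d1"))
        assert not np.array_equal(seq, rev)

    def test_unknown_drug_id_is_named_in_the_error(self, toy_features):
        with pytest.raises(KeyError, match="zzz"):
            make_pair_sequence(toy_features, ("d1", "zzz"))
        with pytest.raises(KeyError, match="zzz"):
            pair_design_matrix(toy_features, [("zzz", "d1")])

    def test_design_matrix_is_concatenation(self, toy_features):
        X = pair_design_matrix(toy_features, [("d1", "d3"), ("d3", "d1")])
        np.testing.assert_array_equal(X[0], [1.0, 0.0, 2.0, 2.0])
        np.testing.assert_array_equal(X[1], [2.0, 2.0, 1.0, 0.0])
        assert X.shape[1] == 2 * toy_features.matrix.shape[1]


def _separable_pairs(rng, n_per=30):
    """Four prototype pair inputs, one per planted type."""
    protos = {
        "t0": (np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0])),
        "t1": (np.array([0.0, 1.0, 0.0]), np.array([1.0, 0.0, 0.0])),
        "t2": (np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0])),
        "t3": (np.array([1.0, 0.0, 0.0]), np.array([0.0, 0.0, 1.0])),
    }
    X, y = [], []
    for label, (a, b) in protos.items():
        for _ in range(n_per):
            X.append(np.concatenate([a, b]))
            y.append(label)
    X = np.array(X)
    y = np.array(y)
    order = rng.permutation(len(y))
    return X[order], y[order]


@pytest.mark.parametrize("cls,kw", [
    (LSTMDdiClassifier, dict(units=32)),
    (DNNDdiClassifier, dict(hidden_layers=(32,))),
])
class TestClassifiers:
    def test_learns_separable_planted_types(self, cls, kw, rng):
        X, y = _separable_pairs(rng)
        model = cls(epochs=2000, early_stopping=False, random_state=0, **kw)
        model.fit(X, y)
        acc = (model.predict(X) == y).mean()
        assert acc >= 0.99
        decided = model.decide_labels(X)
        assert decided.shape == (len(y), 4)
        assert (decided.sum(axis=1) >= 1).all()

    def test_same_seed_gives_identical_predictions(self, cls, kw, rng):
        X, y = _separable_pairs(rng, n_per=10)
        a = cls(epochs=30, random_state=4, **kw).fit(X, y)
        b = cls(epochs=30, random_state=4, **kw).fit(X, y)
        np.testing.assert_array_equal(a.predict_proba(X), b.predict_proba(X))
        np.testing.assert_array_equal(a.loss_trace_, b.loss_trace_)

    def test_single_type_dataset_predicts_that_type(self, cls, kw, rng):
        X = rng.standard_normal((20, 6))
        y = np.array(["only"] * 20)
        model = cls(epochs=50, random_state=0, **kw).fit(X, y)
        assert set(model.predict(X)) == {"only"}

    def test_checkpoint_round_trip_preserves_predictions(self, cls, kw, rng, tmp_path):
        X, y = _separable_pairs(rng, n_per=8)
        model = cls(epochs=30, random_state=3, **kw).fit(X, y)
        model.save(tmp_path / "ckpt")
        again = cls.load(tmp_path / "ckpt")
        np.testing.assert_array_equal(again.predict_proba(X), model.predict_proba(X))
        assert list(again.classes_) == list(model.classes_)

    def test_scores_are_probabilities_and_inference_is_batch_invariant(self, cls, kw, rng):
        X, y = _separable_pairs(rng, n_per=8)
        model = cls(epochs=40, random_state=1, **kw).fit(X, y)
        scores = model.predict_proba(X)
        assert ((scores >= 0.0) & (scores <= 1.0)).all()
        perm = rng.permutation(len(X))
        np.testing.assert_allclose(model.predict_proba(X[perm]), scores[perm],
                                   atol=1e-12)


class TestDecoding:
    def test_argmax_fallback_when_no_score_passes_threshold(self, rng):
        X, y = _separable_pairs(rng, n_per=8)
        model = LSTMDdiClassifier(units=8, epochs=2, random_state=0,
                                  threshold=1.01).fit(X, y)
        decided = model.decide_labels(X)
        # impossible threshold: every row falls back to exactly the arg-max
        assert (decided.sum(axis=1) == 1).all()
        np.testing.assert_array_equal(
            np.argmax(model.predict_proba(X), axis=1), np.argmax(decided, axis=1)
        )


def test_order_sensitivity_of_the_sequence_model(rng):
    """(a, b) and (b, a) produce different LSTM inputs, hence can differ."""
    X, y = _separable_pairs(rng, n_per=20)
    model = LSTMDdiClassifier(units=32, epochs=2000, early_stopping=False,
                              random_state=2).fit(X, y)
    # t0 and t1 are the same two drugs in opposite order
    x_ab = X[y == "t0"][:1]
    x_ba = x_ab.reshape(1, 2, 3)[:, ::-1].reshape(1, 6)
    assert model.predict(x_ab)[0] == "t0"
    assert model.predict(x_ba)[0] == "t1"


def test_dnn_concatenation_width_is_twice_feature_dim(toy_features):
    X = pair_design_matrix(toy_features, [("d1", "d2")])
    model = DNNDdiClassifier(hidden_layers=(8,), epochs=2, random_state=0)
    model.fit(np.vstack([X, X + 1.0]), np.array(["a", "b"]))
    assert model.n_features_in_ == 4
    with pytest.raises(ValueError):
        LSTMDdiClassifier(units=4, epochs=1).fit(np.ones((4, 5)), np.array(list("abab")))
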