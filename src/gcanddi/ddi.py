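"""DDI-type classifiers over ordered drug pairs.

An interaction often consists of one drug modifying the effect of the other,
so a pair is treated as a *sequence* of two drug-feature vectors and modelled
with a stacked LSTM (two layers of 400 units by default, forget-gate bias
0.7); the final hidden state feeds a sigmoid output head with one unit per
interaction type, trained with per-type binary cross-entropy. A
concatenation DNN over ``[f(a), f(b)]`` with the same head serves as the
order-insensitive baseline.

Decoding is multi-label: every type whose score passes the threshold (0.5)
is predicted; when none passes, the arg-max type is returned so every pair
receives at least one label.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split

from ._nn import Adam, binary_cross_entropy, dropout_mask, glorot_uniform, sigmoid
from .gcan import EmbeddedFeatures

__all__ = [
    "make_pair_sequence",
    "pair_design_matrix",
    "LSTMDdiClassifier",
    "DNNDdiClassifier",
    "fit_classical_baseline",
]


class TrainingDivergedError(RuntimeError):
    pass


def make_pair_sequence(features: EmbeddedFeatures, pair: tuple[str, str]) -> np.ndarray:
    """Length-2 sequence [f(drug_a), f(drug_b)] for one ordered pair."""
    a, b = pair[0], pair[1]
    return np.stack([features.row(a), features.row(b)])


def pair_design_matrix(features: EmbeddedFeatures, pairs) -> np.ndarray:
    """(n_pairs, 2*d) design matrix of concatenated pair features.

    ``pairs`` is a DataFrame with ``drug_a``/``drug_b`` columns (or any
    iterable of ordered id pairs). The first d columns are drug_a's vector
    and the last d drug_b's; the sequence classifiers split them back into
    two steps internally, so one matrix serves every model.
    """
    if hasattr(pairs, "itertuples"):
        pair_list = [(r.drug_a, r.drug_b) for r in pairs.itertuples()]
    else:
        pair_list = [(a, b) for a, b in pairs]
    index = {d: i for i, d in enumerate(features.drug_ids)}
    rows = np.empty((len(pair_list), 2 * features.matrix.shape[1]))
    d = features.matrix.shape[1]
    for i, (a, b) in enumerate(pair_list):
        if a not in index:
            raise KeyError(f"unknown drug id: {a!r}")
        if b not in index:
            raise KeyError(f"unknown drug id: {b!r}")
        rows[i, :d] = features.matrix[index[a]]
        rows[i, d:] = features.matrix[index[b]]
    return rows


# --------------------------------------------------------------------------
# recurrent layer


class _LSTMLayer:
    """One LSTM layer over short sequences, with explicit backpropagation.

    Gate order in the packed weight matrices is [input, forget, cell,
    output]. The forget-gate bias is initialised to ``forget_bias`` so the
    cell starts out retaining most of its memory.
    """

    def __init__(self, rng: np.random.Generator, input_dim: int, units: int,
                 forget_bias: float):
        self.units = units
        self.Wx = glorot_uniform(rng, input_dim, 4 * units)
        self.Wh = self._orthogonal(rng, units)
        self.b = np.zeros(4 * units)
        self.b[units:2 * units] = forget_bias

    @staticmethod
    def _orthogonal(rng: np.random.Generator, units: int) -> np.ndarray:
        blocks = []
        for _ in range(4):
            q, r = np.linalg.qr(rng.standard_normal((units, units)))
            blocks.append(q * np.sign(np.diag(r)))
        return np.concatenate(blocks, axis=1)

    def params(self) -> list[np.ndarray]:
        return [self.Wx, self.Wh, self.b]

    def forward(self, x_seq: np.ndarray):
        """x_seq: (B, T, d) -> h_seq (B, T, units) plus a backward cache."""
        B, T, _ = x_seq.shape
        U = self.units
        h = np.zeros((B, U))
        c = np.zeros((B, U))
        h_seq = np.empty((B, T, U))
        cache = []
        for t in range(T):
            z = x_seq[:, t] @ self.Wx + h @ self.Wh + self.b
            i = sigmoid(z[:, :U])
            f = sigmoid(z[:, U:2 * U])
            g = np.tanh(z[:, 2 * U:3 * U])
            o = sigmoid(z[:, 3 * U:])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            cache.append((x_seq[:, t], h, c, i, f, g, o, tanh_c))
            h, c = h_new, c_new
            h_seq[:, t] = h
        return h_seq, cache

    def backward(self, cache, dh_seq: np.ndarray):
        """Backprop through time; returns (dWx, dWh, db) and dX_seq."""
        B, T, _ = dh_seq.shape
        U = self.units
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dX = np.empty((B, T, self.Wx.shape[0]))
        dh_next = np.zeros((B, U))
        dc_next = np.zeros((B, U))
        for t in reversed(range(T)):
            x_t, h_prev, c_prev, i, f, g, o, tanh_c = cache[t]
            dh = dh_seq[:, t] + dh_next
            do = dh * tanh_c
            dc = dh * o * (1 - tanh_c * tanh_c) + dc_next
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dc_next = dc * f
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
                axis=1,
            )
            dWx += x_t.T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dX[:, t] = dz @ self.Wx.T
            dh_next = dz @ self.Wh.T
        return [dWx, dWh, db], dX


# --------------------------------------------------------------------------
# shared training loop


class _BaseDdiNet(BaseEstimator, ClassifierMixin):
    """Minibatch Adam training with multi-label BCE loss and seeded dropout."""

    # subclasses define: _build(input_dim, n_out, rng), _params(),
    # _l2_matrices(), _forward(X, rng or None), _backward(cache, dlogits)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_BaseDdiNet":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n_pairs, 2*d) aligned with y")
        self.classes_ = np.unique(y)
        Y = self._binarize(y)
        rng = np.random.default_rng(self.random_state)
        self._build(X.shape[1], len(self.classes_), rng)
        params = self._params()
        opt = Adam(params, self.learning_rate)

        X_tr, Y_tr, X_val, Y_val = self._split(X, Y, y)
        n = X_tr.shape[0]
        batch = max(1, min(self.batch_size, n))
        trace: list[float] = []
        best, since_best, best_params = np.inf, 0, None
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, batch):
                idx = order[start:start + batch]
                probs, cache = self._forward(X_tr[idx], rng)
                loss = binary_cross_entropy(probs, Y_tr[idx]) + self._penalty()
                if not np.isfinite(loss):
                    raise TrainingDivergedError(f"non-finite loss at epoch {epoch}")
                dlogits = (probs - Y_tr[idx]) / probs.size
                grads = self._backward(cache, dlogits)
                for g, w in zip(grads, params):
                    if any(w is m for m in self._l2_matrices()):
                        g += 2 * self.l2_rate * w
                opt.step(grads)
                losses.append(loss)
            trace.append(float(np.mean(losses)))
            monitor = trace[-1]
            if X_val is not None:
                val_probs, _ = self._forward(X_val, None)
                monitor = binary_cross_entropy(val_probs, Y_val)
            if self.early_stopping:
                if monitor < best - self.min_delta:
                    best, since_best = monitor, 0
                    best_params = [p.copy() for p in params]
                else:
                    since_best += 1
                    if since_best >= self.patience:
                        break
        if self.early_stopping and best_params is not None:
            for p, bp in zip(params, best_params):
                p[...] = bp
        self.loss_trace_ = np.array(trace)
        self.n_features_in_ = X.shape[1]
        return self

    def _split(self, X, Y, y):
        frac = getattr(self, "validation_fraction", 0.0)
        if not self.early_stopping or frac <= 0.0:
            return X, Y, None, None
        n_val = int(round(frac * X.shape[0]))
        if n_val < 1 or X.shape[0] - n_val < len(self.classes_):
            return X, Y, None, None
        counts = Y.sum(axis=0)
        stratify = y if counts.min() >= 2 and n_val >= len(self.classes_) else None
        idx_tr, idx_val = train_test_split(
            np.arange(X.shape[0]), test_size=n_val,
            random_state=self.random_state, stratify=stratify,
        )
        return X[idx_tr], Y[idx_tr], X[idx_val], Y[idx_val]

    def _binarize(self, y: np.ndarray) -> np.ndarray:
        index = {c: j for j, c in enumerate(self.classes_)}
        Y = np.zeros((len(y), len(self.classes_)))
        for i, label in enumerate(y):
            Y[i, index[label]] = 1.0
        return Y

    def _penalty(self) -> float:
        return self.l2_rate * sum(float(np.sum(W * W)) for W in self._l2_matrices())

    # ------------------------------------------------------------ inference

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Per-type sigmoid scores in [0, 1], shape (n_pairs, n_types)."""
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        probs, _ = self._forward(X, None)
        return probs

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Single best type per pair (arg-max score)."""
        scores = self.predict_proba(X)
        return self.classes_[np.argmax(scores, axis=1)]

    def decide_labels(self, X: np.ndarray) -> np.ndarray:
        """Multi-label 0/1 decisions: threshold, arg-max fallback."""
        scores = self.predict_proba(X)
        decided = (scores >= self.threshold).astype(int)
        empty = decided.sum(axis=1) == 0
        decided[empty, np.argmax(scores[empty], axis=1)] = 1
        return decided

    def _check_fitted(self) -> None:
        if not hasattr(self, "classes_"):
            raise RuntimeError("classifier is not fitted yet")

    # ---------------------------------------------------------- checkpoints

    def save(self, directory) -> None:
        """Write a checkpoint: one tensor archive plus a JSON sidecar."""
        import json
        from pathlib import Path

        self._check_fitted()
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        arrays = {f"p{i}": p for i, p in enumerate(self._params())}
        np.savez(directory / "checkpoint.npz", **arrays)
        meta = {
            "params": self.get_params(),
            "classes": [str(c) for c in self.classes_],
            "n_features_in": int(self.n_features_in_),
            "loss_trace": [float(v) for v in self.loss_trace_],
            "class": type(self).__name__,
        }
        with open(directory / "checkpoint.json", "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, directory):
        import json
        from pathlib import Path

        directory = Path(directory)
        with open(directory / "checkpoint.json") as fh:
            meta = json.load(fh)
        params = dict(meta["params"])
        if "hidden_layers" in params and isinstance(params["hidden_layers"], list):
            params["hidden_layers"] = tuple(params["hidden_layers"])
        model = cls(**params)
        model.classes_ = np.array(meta["classes"])
        rng = np.random.default_rng(model.random_state)
        model._build(meta["n_features_in"], len(model.classes_), rng)
        stored = model._params()
        with np.load(directory / "checkpoint.npz") as arc:
            for i, p in enumerate(stored):
                p[...] = arc[f"p{i}"]
        model.n_features_in_ = meta["n_features_in"]
        model.loss_trace_ = np.array(meta["loss_trace"])
        return model


# --------------------------------------------------------------------------
# concrete models


class LSTMDdiClassifier(_BaseDdiNet):
    """Two-step sequence LSTM over ordered drug pairs.

    Defaults follow the reference configuration: two layers of 400 units,
    forget-gate bias 0.7, learning rate 1e-4, dropout 0.5, batch size 256
    and L2 rate 1e-5. ``X`` is the concatenated (n, 2*d) pair matrix from
    :func:`pair_design_matrix`; it is split back into the two time steps
    internally, so pair order matters: (a, b) and (b, a) are different
    inputs.
    """

    def __init__(self, units: int = 400, n_layers: int = 2,
                 forget_bias: float = 0.7, learning_rate: float = 1e-4,
                 dropout: float = 0.5, batch_size: int = 256,
                 l2_rate: float = 1e-5, epochs: int = 300,
                 early_stopping: bool = True, validation_fraction: float = 0.1,
                 patience: int = 30, min_delta: float = 1e-5,
                 threshold: float = 0.5, random_state: int = 0):
        self.units = units
        self.n_layers = n_layers
        self.forget_bias = forget_bias
        self.learning_rate = learning_rate
        self.dropout = dropout
        self.batch_size = batch_size
        self.l2_rate = l2_rate
        self.epochs = epochs
        self.early_stopping = early_stopping
        self.validation_fraction = validation_fraction
        self.patience = patience
        self.min_delta = min_delta
        self.threshold = threshold
        self.random_state = random_state

    def _build(self, input_dim: int, n_out: int, rng) -> None:
        if input_dim % 2 != 0:
            raise ValueError("pair design matrix width must be 2*d")
        d = input_dim // 2
        self.layers_ = []
        in_dim = d
        for _ in range(self.n_layers):
            self.layers_.append(_LSTMLayer(rng, in_dim, self.units, self.forget_bias))
            in_dim = self.units
        self.W_out_ = glorot_uniform(rng, self.units, n_out)
        self.b_out_ = np.zeros(n_out)

    def _params(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers_:
            out.extend(layer.params())
        out.extend([self.W_out_, self.b_out_])
        return out

    def _l2_matrices(self) -> list[np.ndarray]:
        mats = []
        for layer in self.layers_:
            mats.extend([layer.Wx, layer.Wh])
        mats.append(self.W_out_)
        return mats

    def _forward(self, X: np.ndarray, rng):
        B = X.shape[0]
        d = X.shape[1] // 2
        seq = X.reshape(B, 2, d)
        caches, masks = [], []
        h_seq = seq
        for layer in self.layers_:
            h_seq, cache = layer.forward(h_seq)
            if rng is not None and self.dropout > 0:
                mask = dropout_mask(rng, h_seq.shape, self.dropout)
            else:
                mask = None
            caches.append(cache)
            masks.append(mask)
            h_seq = h_seq if mask is None else h_seq * mask
        final = h_seq[:, -1]
        probs = sigmoid(final @ self.W_out_ + self.b_out_)
        return probs, (caches, masks, final)

    def _backward(self, cache, dlogits):
        caches, masks, final = cache
        gW_out = final.T @ dlogits
        gb_out = dlogits.sum(axis=0)
        B = dlogits.shape[0]
        dh_seq = np.zeros((B, 2, self.units))
        dh_seq[:, -1] = dlogits @ self.W_out_.T
        grads_per_layer = []
        d_upper = dh_seq
        for li in reversed(range(len(self.layers_))):
            if masks[li] is not None:
                d_upper = d_upper * masks[li]
            layer_grads, d_upper = self.layers_[li].backward(caches[li], d_upper)
            grads_per_layer.append(layer_grads)
        grads = []
        for layer_grads in reversed(grads_per_layer):
            grads.extend(layer_grads)
        grads.extend([gW_out, gb_out])
        return grads


class DNNDdiClassifier(_BaseDdiNet):
    """Concatenation DNN baseline: [f(a), f(b)] through dense ReLU layers.

    Order information is present only through the concatenation layout; the
    network has no sequence structure. Same sigmoid/BCE head and decoding
    rule as the LSTM so comparisons isolate the architecture.
    """

    def __init__(self, hidden_layers: tuple[int, ...] = (400, 400),
                 learning_rate: float = 1e-4, dropout: float = 0.5,
                 batch_size: int = 256, l2_rate: float = 1e-5,
                 epochs: int = 300, early_stopping: bool = True,
                 validation_fraction: float = 0.1, patience: int = 30,
                 min_delta: float = 1e-5, threshold: float = 0.5,
                 random_state: int = 0):
        self.hidden_layers = hidden_layers
        self.learning_rate = learning_rate
        self.dropout = dropout
        self.batch_size = batch_size
        self.l2_rate = l2_rate
        self.epochs = epochs
        self.early_stopping = early_stopping
        self.validation_fraction = validation_fraction
        self.patience = patience
        self.min_delta = min_delta
        self.threshold = threshold
        self.random_state = random_state

    def _build(self, input_dim: int, n_out: int, rng) -> None:
        dims = [input_dim, *self.hidden_layers, n_out]
        self.Ws_ = [glorot_uniform(rng, dims[i], dims[i + 1]) for i in range(len(dims) - 1)]
        self.bs_ = [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)]

    def _params(self) -> list[np.ndarray]:
        return [*self.Ws_, *self.bs_]

    def _l2_matrices(self) -> list[np.ndarray]:
        return list(self.Ws_)

    def _forward(self, X: np.ndarray, rng):
        h = X
        pre_drop, masks = [], []
        for W, b in zip(self.Ws_[:-1], self.bs_[:-1]):
            a = np.maximum(h @ W + b, 0.0)
            if rng is not None and self.dropout > 0:
                mask = dropout_mask(rng, a.shape, self.dropout)
            else:
                mask = None
            pre_drop.append((h, a))
            masks.append(mask)
            h = a if mask is None else a * mask
        probs = sigmoid(h @ self.Ws_[-1] + self.bs_[-1])
        return probs, (pre_drop, masks, h)

    def _backward(self, cache, dlogits):
        pre_drop, masks, last_h = cache
        gWs = [np.empty(0)] * len(self.Ws_)
        gbs = [np.empty(0)] * len(self.bs_)
        gWs[-1] = last_h.T @ dlogits
        gbs[-1] = dlogits.sum(axis=0)
        dh = dlogits @ self.Ws_[-1].T
        for li in reversed(range(len(self.Ws_) - 1)):
            inp, act = pre_drop[li]
            if masks[li] is not None:
                dh = dh * masks[li]
            dh = dh * (act > 0)
            gWs[li] = inp.T @ dh
            gbs[li] = dh.sum(axis=0)
            dh = dh @ self.Ws_[li].T
        return [*gWs, *gbs]


def fit_classical_baseline(estimator, X: np.ndarray, y: np.ndarray):
    """Adapter seam for classical multi-label baselines.

    Fits any scikit-learn-compatible estimator (e.g.
    ``RandomForestClassifier`` with library defaults) on the concatenated
    pair matrix and single-type labels, and returns it. Kept deliberately
    thin: the classical methods are comparison points, not part of the
    model.
    """
    return estimator.fit(np.asarray(X, dtype=float), np.asarray(y))
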