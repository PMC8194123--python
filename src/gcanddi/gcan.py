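"""Graph-convolutional autoencoder embedding of transcriptome signatures.

The encoder maps each drug's 977-dimensional differential-expression
signature through two graph-convolutional layers (977 -> 640 -> 512); the
decoder maps the 512-dimensional embedding back up (512 -> 640 -> 1024) to a
per-bit probability of the drug's Morgan fingerprint. Each layer first mixes
every drug's features with those of its most structurally similar neighbours
by multiplying with the row-stochastic similarity-graph weights, then applies
a dense map and a nonlinearity (tanh on hidden layers; sigmoid on the output
layer so a per-bit cross-entropy against the fingerprint is well defined).

Training the decoder to reconstruct chemical structure forces the embedding
to retain the structure-related component of the noisy expression data; with
the identity graph the same network is a plain (non-graph) autoencoder
baseline.

All training is full-batch (a drug cohort easily fits in memory), seeded,
and implemented directly on NumPy arrays, which keeps runs bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from ._nn import Adam, binary_cross_entropy, dropout_mask, glorot_uniform, resolve_activation, sigmoid
from .chem import SimilarityGraph

__all__ = [
    "graph_conv_layer",
    "EmbeddedFeatures",
    "GCANEmbedder",
    "AutoencoderEmbedder",
    "train_gcan",
    "embed",
]


@dataclass
class EmbeddedFeatures:
    """Row-aligned drug feature matrix with its identifier order.

    ``kind`` tags the feature space (``original``, ``autoencoder`` or
    ``gcan``) so downstream result tables can name it.
    """

    drug_ids: list[str]
    matrix: np.ndarray
    kind: str = "gcan"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.drug_ids):
            raise ValueError("matrix rows must align with drug_ids")
        if not np.isfinite(self.matrix).all():
            raise ValueError("feature matrix contains non-finite entries")

    def row(self, drug_id: str) -> np.ndarray:
        try:
            return self.matrix[self.drug_ids.index(drug_id)]
        except ValueError:
            raise KeyError(f"unknown drug id: {drug_id!r}") from None


class TrainingDivergedError(RuntimeError):
    pass


def graph_conv_layer(weights: np.ndarray | SimilarityGraph, features: np.ndarray,
                     theta: np.ndarray, bias: np.ndarray | float = 0.0,
                     activation="tanh") -> np.ndarray:
    """One graph-convolution: ``activation(W_graph @ features @ theta + bias)``.

    Row i of the output combines the feature rows of drug i's neighbours,
    weighted by the graph edges, before the dense map and the nonlinearity.
    """
    w = weights.weights if isinstance(weights, SimilarityGraph) else np.asarray(weights)
    features = np.asarray(features, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if w.shape[0] != w.shape[1] or w.shape[1] != features.shape[0]:
        raise ValueError("graph row order must match feature rows")
    if features.shape[1] != theta.shape[0]:
        raise ValueError(
            f"feature dim {features.shape[1]} does not match theta rows {theta.shape[0]}"
        )
    act = resolve_activation(activation)
    return act(w @ features @ theta + bias)


class GCANEmbedder(BaseEstimator, TransformerMixin):
    """Graph-convolutional autoencoder, scikit-learn transformer style.

    Parameters
    ----------
    hidden_dim, embed_dim:
        Widths of the intermediate and embedding layers (defaults 640/512,
        the architecture used throughout the package). The input width is
        taken from ``X`` and the output width from ``y`` at fit time.
    learning_rate, l2_rate, dropout:
        Adam step size (1e-4), L2 penalty weight on the dense maps (1e-5)
        and dropout rate on hidden layers during training (0.3).
    epochs, early_stopping, patience, min_delta:
        Full-batch epoch budget (default 500) with optional plateau-based
        early stopping on the training loss.
    random_state:
        Seeds initialisation and dropout; identical seeds give identical
        loss traces and embeddings.

    Attributes
    ----------
    weights_, biases_ : list of layer parameter arrays (encoder then decoder)
    loss_trace_ : per-epoch total training loss (cross-entropy + L2 penalty)
    embedding_ : (n, embed_dim) embedding of the fitted cohort
    """

    def __init__(self, hidden_dim: int = 640, embed_dim: int = 512,
                 learning_rate: float = 1e-4, l2_rate: float = 1e-5,
                 dropout: float = 0.3, epochs: int = 500,
                 early_stopping: bool = True, patience: int = 20,
                 min_delta: float = 1e-5, random_state: int = 0):
        self.hidden_dim = hidden_dim
        self.embed_dim = embed_dim
        self.learning_rate = learning_rate
        self.l2_rate = l2_rate
        self.dropout = dropout
        self.epochs = epochs
        self.early_stopping = early_stopping
        self.patience = patience
        self.min_delta = min_delta
        self.random_state = random_state

    # ------------------------------------------------------------------ fit

    def fit(self, X: np.ndarray, y: np.ndarray,
            graph: SimilarityGraph | np.ndarray | None = None) -> "GCANEmbedder":
        """Train on signatures ``X`` (n, sig_dim) against fingerprints ``y``.

        ``graph`` is the row-stochastic similarity graph over the same n
        drugs; ``None`` means the identity graph (autoencoder baseline).
        """
        X = np.asarray(X, dtype=float)
        Y = np.asarray(y, dtype=float)
        if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
            raise ValueError("X and y must be row-aligned 2-D arrays")
        A = self._graph_matrix(graph, X.shape[0])

        rng = np.random.default_rng(self.random_state)
        dims = [X.shape[1], self.hidden_dim, self.embed_dim, self.hidden_dim, Y.shape[1]]
        self.weights_ = [glorot_uniform(rng, dims[i], dims[i + 1]) for i in range(4)]
        self.biases_ = [np.zeros(dims[i + 1]) for i in range(4)]
        opt = Adam(self.weights_ + self.biases_, self.learning_rate)

        n = X.shape[0]
        trace: list[float] = []
        best, since_best = np.inf, 0
        for epoch in range(self.epochs):
            loss = self._step(X, Y, A, rng, opt, n)
            if not np.isfinite(loss):
                raise TrainingDivergedError(f"non-finite loss at epoch {epoch}")
            trace.append(loss)
            if self.early_stopping:
                if loss < best - self.min_delta:
                    best, since_best = loss, 0
                else:
                    since_best += 1
                    if since_best >= self.patience:
                        break
        self.loss_trace_ = np.array(trace)
        self.n_features_in_ = X.shape[1]
        self.graph_ = A
        self.embedding_ = self.transform(X, graph=A)
        return self

    def _step(self, X, Y, A, rng, opt, n) -> float:
        W1, W2, W3, W4 = self.weights_
        b1, b2, b3, b4 = self.biases_
        # forward with inverted dropout on hidden-layer outputs
        AX = A @ X
        H1 = np.tanh(AX @ W1 + b1)
        M1 = dropout_mask(rng, H1.shape, self.dropout)
        D1 = H1 * M1
        AD1 = A @ D1
        H2 = np.tanh(AD1 @ W2 + b2)
        M2 = dropout_mask(rng, H2.shape, self.dropout)
        D2 = H2 * M2
        AD2 = A @ D2
        H3 = np.tanh(AD2 @ W3 + b3)
        M3 = dropout_mask(rng, H3.shape, self.dropout)
        D3 = H3 * M3
        AD3 = A @ D3
        P = sigmoid(AD3 @ W4 + b4)

        data_loss = binary_cross_entropy(P, Y)
        penalty = self.l2_rate * sum(float(np.sum(W * W)) for W in self.weights_)
        # backward
        dZ4 = (P - Y) / P.size
        gW4 = AD3.T @ dZ4 + 2 * self.l2_rate * W4
        gb4 = dZ4.sum(axis=0)
        dD3 = A.T @ (dZ4 @ W4.T)
        dZ3 = dD3 * M3 * (1 - H3 * H3)
        gW3 = AD2.T @ dZ3 + 2 * self.l2_rate * W3
        gb3 = dZ3.sum(axis=0)
        dD2 = A.T @ (dZ3 @ W3.T)
        dZ2 = dD2 * M2 * (1 - H2 * H2)
        gW2 = AD1.T @ dZ2 + 2 * self.l2_rate * W2
        gb2 = dZ2.sum(axis=0)
        dD1 = A.T @ (dZ2 @ W2.T)
        dZ1 = dD1 * M1 * (1 - H1 * H1)
        gW1 = AX.T @ dZ1 + 2 * self.l2_rate * W1
        gb1 = dZ1.sum(axis=0)
        opt.step([gW1, gW2, gW3, gW4, gb1, gb2, gb3, gb4])
        return data_loss + penalty

    # ------------------------------------------------------------ inference

    def transform(self, X: np.ndarray,
                  graph: SimilarityGraph | np.ndarray | None = None) -> np.ndarray:
        """Deterministic (n, embed_dim) embedding; dropout disabled."""
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("signature width differs from the fitted width")
        A = self.graph_ if graph is None else self._graph_matrix(graph, X.shape[0])
        if A.shape[0] != X.shape[0]:
            raise ValueError("graph size does not match the number of drugs")
        W1, W2 = self.weights_[0], self.weights_[1]
        b1, b2 = self.biases_[0], self.biases_[1]
        H1 = np.tanh(A @ X @ W1 + b1)
        return np.tanh(A @ H1 @ W2 + b2)

    def reconstruct(self, X: np.ndarray,
                    graph: SimilarityGraph | np.ndarray | None = None) -> np.ndarray:
        """Per-bit fingerprint probabilities from the full autoencoder."""
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        A = self.graph_ if graph is None else self._graph_matrix(graph, X.shape[0])
        H2 = self.transform(X, graph=A)
        H3 = np.tanh(A @ H2 @ self.weights_[2] + self.biases_[2])
        return sigmoid(A @ H3 @ self.weights_[3] + self.biases_[3])

    def reconstruction_accuracy(self, X: np.ndarray, y: np.ndarray,
                                graph=None) -> float:
        """Mean per-bit accuracy of thresholded fingerprint reconstruction."""
        probs = self.reconstruct(X, graph=graph)
        return float(np.mean((probs >= 0.5) == (np.asarray(y) >= 0.5)))

    # -------------------------------------------------------------- helpers

    # ---------------------------------------------------------- checkpoints

    def save(self, directory) -> None:
        """Write a checkpoint: one tensor archive plus a JSON sidecar."""
        import json
        from pathlib import Path

        self._check_fitted()
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        arrays = {f"W{i}": w for i, w in enumerate(self.weights_)}
        arrays.update({f"b{i}": b for i, b in enumerate(self.biases_)})
        arrays["graph"] = self.graph_
        np.savez(directory / "checkpoint.npz", **arrays)
        meta = {
            "params": self.get_params(),
            "n_features_in": int(self.n_features_in_),
            "loss_trace": [float(v) for v in self.loss_trace_],
            "class": type(self).__name__,
        }
        with open(directory / "checkpoint.json", "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, directory) -> "GCANEmbedder":
        import json
        from pathlib import Path

        directory = Path(directory)
        with open(directory / "checkpoint.json") as fh:
            meta = json.load(fh)
        model = cls(**meta["params"])
        with np.load(directory / "checkpoint.npz") as arc:
            model.weights_ = [arc[f"W{i}"] for i in range(4)]
            model.biases_ = [arc[f"b{i}"] for i in range(4)]
            model.graph_ = arc["graph"]
        model.n_features_in_ = meta["n_features_in"]
        model.loss_trace_ = np.array(meta["loss_trace"])
        return model

    @staticmethod
    def _graph_matrix(graph, n: int) -> np.ndarray:
        if graph is None:
            return np.eye(n)
        w = graph.weights if isinstance(graph, SimilarityGraph) else np.asarray(graph, dtype=float)
        if w.shape != (n, n):
            raise ValueError(f"graph must be ({n}, {n}); got {w.shape}")
        return w

    def _check_fitted(self) -> None:
        if not hasattr(self, "weights_"):
            raise RuntimeError("this GCANEmbedder instance is not fitted yet")


class AutoencoderEmbedder(GCANEmbedder):
    """Non-graph autoencoder baseline: the same network on the identity graph.

    Embeds signatures under the same fingerprint-reconstruction loss but
    without neighbour mixing, isolating the contribution of the similarity
    graph.
    """

    def fit(self, X, y, graph=None):  # graph intentionally ignored
        return super().fit(X, y, graph=None)

    def transform(self, X, graph=None):
        return super().transform(X, graph=np.eye(np.asarray(X).shape[0]))


def train_gcan(signatures: np.ndarray, fingerprints: np.ndarray,
               graph: SimilarityGraph | np.ndarray, **params) -> GCANEmbedder:
    """Functional wrapper: fit a :class:`GCANEmbedder` and return it."""
    return GCANEmbedder(**params).fit(signatures, fingerprints, graph=graph)


def embed(model: GCANEmbedder, signatures: np.ndarray,
          graph: SimilarityGraph | np.ndarray | None = None) -> np.ndarray:
    """Functional wrapper over :meth:`GCANEmbedder.transform`."""
    return model.transform(signatures, graph=graph)
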