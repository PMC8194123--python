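"""Small seeded neural-network primitives on NumPy arrays.

Everything here is deliberately plain float64 NumPy: the networks in this
package are small (hundreds of drugs, thousands of pairs), so full-precision
CPU training is fast, and keeping all trainable state in explicit arrays makes
runs bit-reproducible from a single integer seed.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit as sigmoid  # numerically stable logistic

__all__ = [
    "sigmoid",
    "glorot_uniform",
    "binary_cross_entropy",
    "dropout_mask",
    "Adam",
    "ACTIVATIONS",
    "resolve_activation",
]

_EPS = 1e-12


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                   shape: tuple[int, ...] | None = None) -> np.ndarray:
    """Glorot/Xavier uniform initialisation, seeded through ``rng``."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    if shape is None:
        shape = (fan_in, fan_out)
    return rng.uniform(-limit, limit, size=shape)


def binary_cross_entropy(probs: np.ndarray, targets: np.ndarray) -> float:
    """Mean per-bit binary cross-entropy between probabilities and 0/1 targets."""
    p = np.clip(probs, _EPS, 1.0 - _EPS)
    return float(-np.mean(targets * np.log(p) + (1.0 - targets) * np.log(1.0 - p)))


def dropout_mask(rng: np.random.Generator, shape: tuple[int, ...],
                 rate: float) -> np.ndarray:
    """Inverted-dropout mask: zeros with probability ``rate``, kept units scaled
    by 1/(1-rate) so expectations match inference."""
    if rate <= 0.0:
        return np.ones(shape)
    keep = 1.0 - rate
    return (rng.random(shape) < keep) / keep


def _identity(x: np.ndarray) -> np.ndarray:
    return x


ACTIVATIONS = {
    "tanh": np.tanh,
    "sigmoid": sigmoid,
    "linear": _identity,
    "identity": _identity,
}


def resolve_activation(activation):
    """Accept an activation by name or as a callable."""
    if callable(activation):
        return activation
    try:
        return ACTIVATIONS[activation]
    except KeyError:
        raise ValueError(
            f"unknown activation {activation!r}; expected one of "
            f"{sorted(ACTIVATIONS)} or a callable"
        ) from None


class Adam:
    """Adam optimiser over a flat list of parameter arrays (updated in place)."""

    def __init__(self, params: list[np.ndarray], learning_rate: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        if len(grads) != len(self.params):
            raise ValueError("gradient list does not match parameter list")
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * np.square(g)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
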