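"""Minimal numpy neural-network primitives: dense layers with manual
gradients and an Adam optimizer.

Everything runs on plain float64 numpy so training is bitwise-reproducible
under a fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["glorot", "Adam", "relu", "drelu", "sigmoid", "softplus"]


def glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    """Glorot-uniform weight initialization."""
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def drelu(x: np.ndarray) -> np.ndarray:
    return (x > 0.0).astype(x.dtype)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


class Adam:
    """Adam optimizer over a dict of named parameter arrays."""

    def __init__(self, params: dict, lr: float = 1e-3, b1: float = 0.9,
                 b2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1.0 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1.0 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps
            )
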