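"""Minimal dense-network building blocks shared by the two autoencoders.

The models here are small MLPs (two dense layers per stage), so forward and
backward passes are written out explicitly in numpy rather than pulling in a
deep-learning framework.  All randomness flows through an explicit
``numpy.random.Generator``, which makes training bit-reproducible on a single
device.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Dense", "Adam", "relu", "relu_grad", "softplus", "softplus_grad", "minibatches"]


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def relu_grad(pre: np.ndarray) -> np.ndarray:
    return (pre > 0).astype(pre.dtype)


def softplus(x: np.ndarray) -> np.ndarray:
    # log(1 + e^x), stable for large |x|
    return np.logaddexp(0.0, x)


def softplus_grad(pre: np.ndarray) -> np.ndarray:
    # sigmoid(pre)
    out = np.empty_like(pre)
    pos = pre >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-pre[pos]))
    ex = np.exp(pre[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Dense:
    """A fully connected layer holding its parameters and their Adam slots."""

    def __init__(self, rng: np.random.Generator, fan_in: int, fan_out: int):
        # He initialisation suits the ReLU stacks used throughout.
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
        self.b = np.zeros(fan_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x @ self.W + self.b

    def backward(self, x: np.ndarray, grad_out: np.ndarray) -> np.ndarray:
        """Accumulate parameter grads for this call and return grad wrt input."""
        self.dW = x.T @ grad_out
        self.db = grad_out.sum(axis=0)
        return grad_out @ self.W.T

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    @property
    def grads(self) -> list[np.ndarray]:
        return [self.dW, self.db]


class Adam:
    """Adam optimizer over a flat list of parameter arrays (updated in place)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            m_hat = m / (1 - b1 ** self.t)
            v_hat = v / (1 - b2 ** self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def minibatches(n: int, batch_size: int, rng: np.random.Generator):
    """Yield shuffled index batches covering 0..n-1 once."""
    order = rng.permutation(n)
    batch_size = max(1, min(batch_size, n))
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]
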