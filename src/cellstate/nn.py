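"""Minimal dense-network primitives on NumPy.

No deep-learning framework is assumed at runtime, so the handful of
pieces the autoencoder needs — dense layers, leaky-ReLU / tanh, inverted
dropout, Adam, and hand-written backprop for the fixed architecture —
live here.  Everything is float64 and deterministic given a seeded
``numpy.random.Generator``; training on the profile sizes involved runs
in seconds on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def glorot_uniform(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


def leaky_relu(x: np.ndarray, alpha: float) -> np.ndarray:
    return np.where(x >= 0, x, alpha * x)


def leaky_relu_grad(x: np.ndarray, alpha: float) -> np.ndarray:
    return np.where(x >= 0, 1.0, alpha)


@dataclass
class Dense:
    """Affine layer y = xW + b with gradient accumulators."""

    W: np.ndarray
    b: np.ndarray
    gW: np.ndarray = field(init=False)
    gb: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    @classmethod
    def init(cls, rng: np.random.Generator, n_in: int, n_out: int) -> "Dense":
        return cls(W=glorot_uniform(rng, n_in, n_out), b=np.zeros(n_out))

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x @ self.W + self.b

    def backward(self, x: np.ndarray, g_out: np.ndarray) -> np.ndarray:
        """Accumulate parameter gradients and return the input gradient."""
        self.gW += x.T @ g_out
        self.gb += g_out.sum(axis=0)
        return g_out @ self.W.T

    def zero_grad(self) -> None:
        self.gW[...] = 0.0
        self.gb[...] = 0.0

    def copy(self) -> "Dense":
        return Dense(W=self.W.copy(), b=self.b.copy())

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size


class ElementwiseScale(Dense):
    """Per-feature learned gain y = x * w (the output-layer skip leak).

    Stored as a (1, n) weight row with an empty bias so it slots into the
    same optimizer machinery as :class:`Dense`.
    """

    @classmethod
    def init(cls, rng: np.random.Generator, n_in: int, n_out: int | None = None
             ) -> "ElementwiseScale":
        return cls(W=np.zeros((1, n_in)), b=np.zeros(0))

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x * self.W[0]

    def backward(self, x: np.ndarray, g_out: np.ndarray) -> np.ndarray:
        self.gW[0] += (g_out * x).sum(axis=0)
        return g_out * self.W[0]

    def copy(self) -> "ElementwiseScale":
        return ElementwiseScale(W=self.W.copy(), b=self.b.copy())


class Adam:
    """Adam over a fixed list of :class:`Dense` layers."""

    def __init__(self, layers: list[Dense], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.layers = layers
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [(np.zeros_like(l.W), np.zeros_like(l.b)) for l in layers]
        self.v = [(np.zeros_like(l.W), np.zeros_like(l.b)) for l in layers]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for layer, m, v in zip(self.layers, self.m, self.v):
            for param, grad, mi, vi in ((layer.W, layer.gW, m[0], v[0]),
                                        (layer.b, layer.gb, m[1], v[1])):
                mi *= b1
                mi += (1 - b1) * grad
                vi *= b2
                vi += (1 - b2) * grad * grad
                param -= self.lr * (mi / bias1) / (np.sqrt(vi / bias2) + self.eps)


def dropout_mask(rng: np.random.Generator, shape: tuple[int, ...],
                 rate: float) -> np.ndarray:
    """Inverted-dropout multiplier: zeros with probability ``rate``,
    1/(1-rate) otherwise."""
    if rate <= 0:
        return np.ones(shape)
    keep = rng.random(shape) >= rate
    return keep / (1.0 - rate)
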