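"""Minimal dense neural-network layers with manual backpropagation.

Only what the evidence-matching model needs: dense layers, ReLU, residual
blocks, softmax cross-entropy and Adam. Everything is plain numpy and fully
deterministic given the seeding Generator.
"""

from __future__ import annotations

import numpy as np


class Dense:
    """Fully connected layer. He-initialized; gradients accumulate on backward."""

    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return x @ self.W + self.b, x

    def backward(self, grad: np.ndarray, cache: np.ndarray) -> np.ndarray:
        self.dW += cache.T @ grad
        self.db += grad.sum(axis=0)
        return grad @ self.W.T

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [(self.W, self.dW), (self.b, self.db)]

    def zero_grad(self) -> None:
        self.dW[...] = 0.0
        self.db[...] = 0.0


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


class ResidualBlock:
    """x -> relu(x + W2 relu(W1 x)); the residual unit of the encoder."""

    def __init__(self, rng: np.random.Generator, width: int):
        self.l1 = Dense(rng, width, width)
        self.l2 = Dense(rng, width, width)

    def forward(self, x: np.ndarray):
        h1, c1 = self.l1.forward(x)
        a1 = relu(h1)
        h2, c2 = self.l2.forward(a1)
        pre = x + h2
        return relu(pre), (c1, h1, c2, pre)

    def backward(self, grad: np.ndarray, cache) -> np.ndarray:
        c1, h1, c2, pre = cache
        dpre = grad * (pre > 0)
        da1 = self.l2.backward(dpre, c2)
        dh1 = da1 * (h1 > 0)
        dx = self.l1.backward(dh1, c1)
        return dx + dpre

    def params(self):
        return self.l1.params() + self.l2.params()

    def zero_grad(self):
        self.l1.zero_grad()
        self.l2.zero_grad()


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    return float(-np.log(np.maximum(probs[np.arange(len(labels)), labels], 1e-12)).mean())


class Adam:
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = params  # list of (value, grad) array pairs
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
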