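"""Minimal feed-forward network primitives with manual backpropagation.

Only what the deep one-class module needs: dense layers, tanh, a sequential
container and Adam with optional decoupled weight decay on the weight
matrices.  Everything is float64 numpy and seed-deterministic.
"""

from __future__ import annotations

import numpy as np


class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, bias: bool = True):
        scale = np.sqrt(2.0 / (n_in + n_out))
        self.W = rng.normal(0.0, scale, size=(n_in, n_out))
        self.b = np.zeros(n_out) if bias else None
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b) if bias else None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        y = x @ self.W
        if self.b is not None:
            y = y + self.b
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.gW[...] = self._x.T @ grad
        if self.b is not None:
            self.gb[...] = grad.sum(axis=0)
        return grad @ self.W.T

    def parameters(self):
        # (array, grad, weight_decay_applies)
        yield self.W, self.gW, True
        if self.b is not None:
            yield self.b, self.gb, False


class Tanh:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = np.tanh(x)
        return self._y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * (1.0 - self._y**2)

    def parameters(self):
        return iter(())


class Sequential:
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self):
        for layer in self.layers:
            yield from layer.parameters()


class Adam:
    """Adam with decoupled weight decay applied to weight matrices only."""

    def __init__(self, modules, lr: float = 1e-3, weight_decay: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.modules = list(modules)
        self.lr = lr
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p) for p, _, _ in self._params()]
        self._v = [np.zeros_like(p) for p, _, _ in self._params()]

    def _params(self):
        for mod in self.modules:
            yield from mod.parameters()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g, decays) in enumerate(self._params()):
            self._m[i] = b1 * self._m[i] + (1 - b1) * g
            self._v[i] = b2 * self._v[i] + (1 - b2) * g**2
            mhat = self._m[i] / (1 - b1**self.t)
            vhat = self._v[i] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if decays and self.weight_decay > 0:
                p -= self.lr * self.weight_decay * p
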