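"""Minimal feed-forward neural-network primitives on numpy.

Dense, batch-normalization, dropout and activation layers with hand-written
backward passes, an Adam optimizer, and a Sequential container. Everything is
deterministic given the generator passed at construction; dropout draws its
masks from that generator, so a fixed seed reproduces training exactly.
"""

from __future__ import annotations

import copy

import numpy as np


class Layer:
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class Dense(Layer):
    """Affine map with Glorot-uniform initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.w = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x, training):
        if x.shape[1] != self.w.shape[0]:
            raise ValueError(
                f"input width {x.shape[1]} does not match layer width {self.w.shape[0]}"
            )
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.dw[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.w.T

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


class Sigmoid(Layer):
    def forward(self, x, training):
        self._out = 1.0 / (1.0 + np.exp(-x))
        return self._out

    def backward(self, grad):
        return grad * self._out * (1.0 - self._out)


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class BatchNorm(Layer):
    """Per-feature batch normalization with running statistics for inference."""

    def __init__(self, n: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(n)
        self.beta = np.zeros(n)
        self.dgamma = np.zeros(n)
        self.dbeta = np.zeros(n)
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, training):
        if training:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
            self._std = np.sqrt(var + self.eps)
            self._xhat = (x - mu) / self._std
            return self.gamma * self._xhat + self.beta
        xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return self.gamma * xhat + self.beta

    def backward(self, grad):
        n = grad.shape[0]
        self.dgamma[...] = (grad * self._xhat).sum(axis=0)
        self.dbeta[...] = grad.sum(axis=0)
        dxhat = grad * self.gamma
        return (
            dxhat - dxhat.mean(axis=0) - self._xhat * (dxhat * self._xhat).mean(axis=0)
        ) / self._std

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]


class Dropout(Layer):
    """Inverted dropout; identity at inference and at rate 0."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, training):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]

    def state(self) -> list[np.ndarray]:
        """Deep copy of every array that defines inference behaviour."""
        arrays = []
        for layer in self.layers:
            arrays.extend(layer.params())
            if isinstance(layer, BatchNorm):
                arrays.extend([layer.running_mean, layer.running_var])
        return copy.deepcopy(arrays)

    def load_state(self, arrays: list[np.ndarray]) -> None:
        it = iter(arrays)
        for layer in self.layers:
            for p in layer.params():
                p[...] = next(it)
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = next(it)
                layer.running_var[...] = next(it)


class Adam:
    """Adam with the standard bias correction; updates arrays in place."""

    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray],
                 lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params, self.grad_refs = params, grads
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, g, m, v in zip(self.params, self.grad_refs, self.m, self.v):
            m[...] = self.beta1 * m + (1 - self.beta1) * g
            v[...] = self.beta2 * v + (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.log(np.maximum(p[np.arange(n), y], 1e-300)).mean()
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return float(loss), grad / n
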