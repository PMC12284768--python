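"""Minimal reverse-mode layers and an Adam optimizer on numpy arrays.

Every layer caches what its backward pass needs during ``forward`` and
returns the gradient with respect to its input from ``backward``, after
stashing parameter gradients on itself.  Training here is always
full-batch, so a single cached forward per layer suffices.  The
backward implementations are exercised by finite-difference checks in
the test suite.
"""

from __future__ import annotations

import numpy as np


class Layer:
    params: list[np.ndarray]

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    @property
    def grads(self) -> list[np.ndarray]:
        return []


class Dense(Layer):
    """Affine map x @ W + b with He-style initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 bias: bool = True, scale: float | None = None):
        s = np.sqrt(2.0 / n_in) if scale is None else scale
        self.W = rng.normal(0.0, s, size=(n_in, n_out))
        self.b = np.zeros(n_out) if bias else None
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b) if bias else None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        y = x @ self.W
        if self.b is not None:
            y = y + self.b
        return y

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.gW = self._x.T @ g
        if self.b is not None:
            self.gb = g.sum(axis=0)
        return g @ self.W.T

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W] if self.b is None else [self.W, self.b]

    @property
    def grads(self) -> list[np.ndarray]:
        return [self.gW] if self.b is None else [self.gW, self.gb]


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._pos = x >= 0
        return np.where(self._pos, x, self.slope * x)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return np.where(self._pos, g, self.slope * g)

    @property
    def params(self) -> list[np.ndarray]:
        return []


class Tanh(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = np.tanh(x)
        return self._y

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * (1.0 - self._y**2)

    @property
    def params(self) -> list[np.ndarray]:
        return []


class BatchNorm(Layer):
    """Feature-wise standardization with learned scale/shift.

    Statistics are always taken over the current batch — the models in
    this package train full-batch, so batch statistics are population
    statistics and no running averages are kept.
    """

    def __init__(self, n_features: int, eps: float = 1e-5):
        self.gamma = np.ones(n_features)
        self.beta = np.zeros(n_features)
        self.eps = eps
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=0)
        var = x.var(axis=0)
        self._std = np.sqrt(var + self.eps)
        self._xc = x - mu
        self._xhat = self._xc / self._std
        return self.gamma * self._xhat + self.beta

    def backward(self, g: np.ndarray) -> np.ndarray:
        n = g.shape[0]
        self.ggamma = (g * self._xhat).sum(axis=0)
        self.gbeta = g.sum(axis=0)
        gxhat = g * self.gamma
        # standard batch-norm backward, d/dx of (x - mean)/std
        return (
            gxhat
            - gxhat.mean(axis=0)
            - self._xhat * (gxhat * self._xhat).mean(axis=0)
        ) / self._std

    @property
    def params(self) -> list[np.ndarray]:
        return [self.gamma, self.beta]

    @property
    def grads(self) -> list[np.ndarray]:
        return [self.ggamma, self.gbeta]


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]


class Adam:
    """Adam over a fixed list of parameter arrays, updated in place."""

    def __init__(self, params: list[np.ndarray], lr: float,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray], lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= lr * mhat / (np.sqrt(vhat) + self.eps)


def accumulate(total: list[np.ndarray] | None, grads: list[np.ndarray]) -> list[np.ndarray]:
    """Sum gradient lists across multiple backward passes of one step."""
    if total is None:
        return [g.copy() for g in grads]
    for t, g in zip(total, grads):
        t += g
    return total
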