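"""Minimal dense-network machinery: layers, MLPs, Adam, gradient checks.

Reverse-mode gradients are written out by hand for the handful of layer
types the model needs (affine, ReLU). Forward passes cache their inputs,
so several backward passes may be run against one forward pass (used for
per-task gradient-norm probes); parameter gradients accumulate until
``zero_grad``.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np


class Dense:
    """Affine layer y = x W + b with He-scaled Gaussian initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        assert self._x is not None, "backward before forward"
        self.gW += self._x.T @ g
        self.gb += g.sum(axis=0)
        return g @ self.W.T

    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]

    def zero_grad(self) -> None:
        self.gW[...] = 0.0
        self.gb[...] = 0.0


class ReLU:
    def __init__(self):
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._mask

    def params(self):
        return []

    def zero_grad(self) -> None:
        pass


class MLP:
    """A chain of Dense layers with ReLU between them (linear output).

    ``widths`` runs input -> hidden... -> output.
    """

    def __init__(self, widths: Sequence[int], rng: np.random.Generator):
        if len(widths) < 2:
            raise ValueError("MLP needs at least input and output widths")
        self.layers: list = []
        for i, (a, b) in enumerate(zip(widths[:-1], widths[1:])):
            self.layers.append(Dense(a, b, rng))
            if i < len(widths) - 2:
                self.layers.append(ReLU())

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    @property
    def last_dense(self) -> Dense:
        return next(l for l in reversed(self.layers) if isinstance(l, Dense))


class Adam:
    """Adam over a fixed list of (parameter, gradient) array pairs.

    Arrays are updated in place; the pairs must keep their identity across
    steps (layers accumulate into the same gradient buffers).
    """

    def __init__(self, params: Sequence[tuple[np.ndarray, np.ndarray]],
                 lr: float = 1e-3, betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]

    def step(self) -> None:
        self.t += 1
        for i, (p, g) in enumerate(self.params):
            if self.weight_decay:
                g = g + self.weight_decay * p
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def numerical_gradient(f: Callable[[], float], param: np.ndarray,
                       eps: float = 1e-5) -> np.ndarray:
    """Central finite-difference gradient of scalar ``f()`` w.r.t. ``param``."""
    g = np.zeros_like(param)
    it = np.nditer(param, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = param[i]
        param[i] = orig + eps
        hi = f()
        param[i] = orig - eps
        lo = f()
        param[i] = orig
        g[i] = (hi - lo) / (2 * eps)
    return g


def grad_norm(pairs: Sequence[tuple[np.ndarray, np.ndarray]]) -> float:
    """Euclidean norm over a collection of gradient arrays."""
    total = 0.0
    for _, g in pairs:
        total += float((g * g).sum())
    return float(np.sqrt(total))
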