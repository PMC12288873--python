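"""Minimal dense-network engine: explicit forward/backward passes and optimizers.

All models in this package are small multilayer perceptrons over binary allele
matrices or latent codes, so a compact engine with hand-written gradients keeps
the whole training path inspectable and dependency-free.  Weights are Glorot
uniform; dropout uses inverted scaling so inference needs no correction.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = [
    "Dense",
    "MLP",
    "RMSProp",
    "Adam",
    "bce_matrix",
    "bce_grad",
]

_EPS = 1e-7


def _activate(name: str, z: np.ndarray, leaky_slope: float) -> np.ndarray:
    if name == "relu":
        return np.maximum(z, 0.0)
    if name == "leaky_relu":
        return np.where(z > 0.0, z, leaky_slope * z)
    if name == "sigmoid":
        return 1.0 / (1.0 + np.exp(-np.clip(z, -60.0, 60.0)))
    if name == "tanh":
        return np.tanh(z)
    if name == "linear":
        return z
    if name == "relu1":  # ReLU capped at 1: clip(z, 0, 1)
        return np.clip(z, 0.0, 1.0)
    raise ValueError(f"unknown activation {name!r}")


def _activate_grad(name: str, z: np.ndarray, a: np.ndarray, leaky_slope: float) -> np.ndarray:
    if name == "relu":
        return (z > 0.0).astype(z.dtype)
    if name == "leaky_relu":
        return np.where(z > 0.0, 1.0, leaky_slope)
    if name == "sigmoid":
        return a * (1.0 - a)
    if name == "tanh":
        return 1.0 - a * a
    if name == "linear":
        return np.ones_like(z)
    if name == "relu1":
        return ((z > 0.0) & (z < 1.0)).astype(z.dtype)
    raise ValueError(f"unknown activation {name!r}")


class Dense:
    """Fully connected layer with an activation and optional (post-activation) dropout."""

    def __init__(
        self,
        n_in: int,
        n_out: int,
        activation: str = "linear",
        dropout: float = 0.0,
        *,
        rng: np.random.Generator,
        leaky_slope: float = 0.01,
    ) -> None:
        if n_in < 1 or n_out < 1:
            raise ValueError("layer dimensions must be >= 1")
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out))
        if activation == "sigmoid":
            # Glorot scaling targets tanh's linear regime; the logistic sigmoid
            # needs the classic 4x gain or signal attenuates ~4x per layer
            self.W *= 4.0
        self.b = np.zeros(n_out)
        self.activation = activation
        self.dropout = float(dropout)
        self.leaky_slope = leaky_slope
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None
        self._z: np.ndarray | None = None
        self._a: np.ndarray | None = None
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool = False, rng: np.random.Generator | None = None) -> np.ndarray:
        self._x = x
        z = x @ self.W + self.b
        a = _activate(self.activation, z, self.leaky_slope)
        self._z, self._a = z, a
        if training and self.dropout > 0.0:
            if rng is None:
                raise ValueError("dropout in training mode requires an rng")
            mask = (rng.random(a.shape) >= self.dropout) / (1.0 - self.dropout)
            self._mask = mask
            return a * mask
        self._mask = None
        return a

    def backward(self, grad: np.ndarray) -> np.ndarray:
        """Gradient wrt layer input; stores dW/db from the cached forward pass."""
        if self._x is None:
            raise RuntimeError("backward called before forward")
        if self._mask is not None:
            grad = grad * self._mask
        gz = grad * _activate_grad(self.activation, self._z, self._a, self.leaky_slope)
        self.dW = self._x.T @ gz
        self.db = gz.sum(axis=0)
        return gz @ self.W.T


class MLP:
    """A stack of Dense layers defined by dims / per-layer activations / dropouts."""

    def __init__(
        self,
        dims: Sequence[int],
        activations: Sequence[str],
        dropouts: Sequence[float] | None = None,
        *,
        rng: np.random.Generator,
        leaky_slope: float = 0.01,
    ) -> None:
        if len(activations) != len(dims) - 1:
            raise ValueError("need one activation per layer")
        if dropouts is None:
            dropouts = [0.0] * len(activations)
        self.layers = [
            Dense(dims[i], dims[i + 1], activations[i], dropouts[i], rng=rng, leaky_slope=leaky_slope)
            for i in range(len(dims) - 1)
        ]

    def forward(self, x: np.ndarray, training: bool = False, rng: np.random.Generator | None = None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training, rng=rng)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for layer in self.layers:
            out.extend((layer.W, layer.b))
        return out

    def gradients(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for layer in self.layers:
            out.extend((layer.dW, layer.db))
        return out

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        if len(weights) != len(params):
            raise ValueError("weight list length mismatch")
        for p, w in zip(params, weights):
            if p.shape != w.shape:
                raise ValueError("weight shape mismatch")
            p[...] = w


class RMSProp:
    """RMSProp with keras-style defaults (rho=0.9, eps=1e-7)."""

    def __init__(self, learning_rate: float, rho: float = 0.9, eps: float = 1e-7) -> None:
        self.lr = learning_rate
        self.rho = rho
        self.eps = eps
        self._cache: dict[int, np.ndarray] = {}

    def step(self, params: Sequence[np.ndarray], grads: Sequence[np.ndarray]) -> None:
        for i, (p, g) in enumerate(zip(params, grads)):
            v = self._cache.get(i)
            if v is None:
                v = np.zeros_like(p)
                self._cache[i] = v
            v *= self.rho
            v += (1.0 - self.rho) * g * g
            p -= self.lr * g / (np.sqrt(v) + self.eps)


class Adam:
    def __init__(self, learning_rate: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7) -> None:
        self.lr = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}
        self._t = 0

    def step(self, params: Sequence[np.ndarray], grads: Sequence[np.ndarray]) -> None:
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1.0 - b2**self._t) / (1.0 - b1**self._t)
        for i, (p, g) in enumerate(zip(params, grads)):
            m = self._m.setdefault(i, np.zeros_like(p))
            v = self._v.setdefault(i, np.zeros_like(p))
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)


def bce_matrix(yhat: np.ndarray, y: np.ndarray, eps: float = _EPS) -> np.ndarray:
    """Elementwise binary cross-entropy; predictions clipped away from {0,1}."""
    yh = np.clip(yhat, eps, 1.0 - eps)
    return -(y * np.log(yh) + (1.0 - y) * np.log1p(-yh))


def bce_grad(yhat: np.ndarray, y: np.ndarray, eps: float = _EPS) -> np.ndarray:
    yh = np.clip(yhat, eps, 1.0 - eps)
    return (yh - y) / (yh * (1.0 - yh))
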