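"""Minimal feedforward building blocks: affine layers, activations,
and the Adam / RMSprop update rules, all in numpy with explicit
backpropagation.  Shared by the collective factorization model and the
denoising-autoencoder baseline."""

from __future__ import annotations

import numpy as np


def _tanh(z):
    return np.tanh(z)


def _dtanh(z, a):
    return 1.0 - a * a


def _linear(z):
    return z


def _dlinear(z, a):
    return np.ones_like(z)


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _dsigmoid(z, a):
    return a * (1.0 - a)


ACTIVATIONS = {
    "tanh": (_tanh, _dtanh),
    "linear": (_linear, _dlinear),
    "sigmoid": (_sigmoid, _dsigmoid),
}


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Affine:
    """One dense layer ``a = act(x W + b)`` with fan-in-scaled uniform init."""

    def __init__(self, n_in: int, n_out: int, activation: str, rng: np.random.Generator):
        if activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {activation!r}")
        bound = 1.0 / np.sqrt(n_in)
        self.W = rng.uniform(-bound, bound, size=(n_in, n_out))
        self.b = rng.uniform(-bound, bound, size=n_out)
        self.activation = activation
        self._x = None
        self._z = None
        self._a = None
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        f, _ = ACTIVATIONS[self.activation]
        self._x = x
        self._z = x @ self.W + self.b
        self._a = f(self._z)
        return self._a

    def backward(self, d_out: np.ndarray) -> np.ndarray:
        """Accumulate dW/db for gradient d_out w.r.t. the activation output;
        return the gradient w.r.t. the layer input."""
        _, df = ACTIVATIONS[self.activation]
        dz = d_out * df(self._z, self._a)
        self.dW += self._x.T @ dz
        self.db += dz.sum(axis=0)
        return dz @ self.W.T

    def zero_grad(self) -> None:
        self.dW[...] = 0.0
        self.db[...] = 0.0

    @property
    def params_and_grads(self):
        return [(self.W, self.dW), (self.b, self.db)]


class MLP:
    """A stack of affine layers."""

    def __init__(self, sizes: list[int], activations: list[str], rng):
        assert len(activations) == len(sizes) - 1
        self.layers = [
            Affine(sizes[i], sizes[i + 1], activations[i], rng)
            for i in range(len(sizes) - 1)
        ]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, d_out: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            d_out = layer.backward(d_out)
        return d_out

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    @property
    def params_and_grads(self):
        return [pg for layer in self.layers for pg in layer.params_and_grads]


class Adam:
    """Adam with optional L2 weight decay added to the gradient."""

    def __init__(self, params_and_grads, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.0):
        self.pg = params_and_grads
        self.lr, self.eps, self.weight_decay = lr, eps, weight_decay
        self.b1, self.b2 = betas
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in self.pg]
        self.v = [np.zeros_like(p) for p, _ in self.pg]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, (p, g) in enumerate(self.pg):
            g = g + self.weight_decay * p
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)


class RMSprop:
    def __init__(self, params_and_grads, lr=1e-3, rho=0.9, eps=1e-8,
                 weight_decay=0.0):
        self.pg = params_and_grads
        self.lr, self.rho, self.eps = lr, rho, eps
        self.weight_decay = weight_decay
        self.sq = [np.zeros_like(p) for p, _ in self.pg]

    def step(self) -> None:
        for i, (p, g) in enumerate(self.pg):
            g = g + self.weight_decay * p
            self.sq[i] = self.rho * self.sq[i] + (1 - self.rho) * g * g
            p -= self.lr * g / (np.sqrt(self.sq[i]) + self.eps)


OPTIMIZERS = {"adam": Adam, "rmsprop": RMSprop}
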