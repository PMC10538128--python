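"""Minimal NumPy neural-network layers with manual backpropagation.

Implements exactly what the reconstruction and classifier networks need:
dense and (transposed) convolution layers, batch normalization, ReLU /
leaky-ReLU / sigmoid activations, dropout, the Adam optimizer and the MSE /
L1 / binary-cross-entropy losses.  All computation is float32; every source
of randomness (initialization, dropout, batching) goes through an explicit
``numpy.random.Generator`` so training is reproducible bit for bit.

Layers follow a simple protocol: ``forward(x, training)`` caches what the
matching ``backward(grad)`` needs; ``params()`` yields (name, value, grad)
triples for the optimizer.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

F32 = np.float32


class Layer:
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self):
        return []

    def state(self) -> dict:
        """Serializable parameter/state arrays."""
        return {name: p for name, p, _ in self.params()}

    def load_state(self, state: dict, prefix: str = "") -> None:
        for name, p, _ in self.params():
            p[...] = state[prefix + name] if prefix else state[name]


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = (rng.standard_normal((n_in, n_out)) * scale).astype(F32)
        self.b = np.zeros(n_out, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, training=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]


class BatchNorm(Layer):
    """Batch normalization over all axes except the feature axis.

    Works for 2D inputs (B, F) with ``axis=1`` and 4D inputs (B, C, H, W)
    with ``axis=1`` (per-channel statistics).
    """

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(n_features, dtype=F32)
        self.beta = np.zeros(n_features, dtype=F32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(n_features, dtype=F32)
        self.running_var = np.ones(n_features, dtype=F32)
        self.momentum = momentum
        self.eps = eps

    def _shape(self, x):
        # broadcastable shape for per-feature arrays
        return (1, -1) + (1,) * (x.ndim - 2)

    def forward(self, x, training=False):
        axes = (0,) + tuple(range(2, x.ndim))
        sh = self._shape(x)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(F32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(F32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(sh)) * inv.reshape(sh)
        self._xhat, self._inv, self._axes, self._sh = xhat, inv, axes, sh
        self._m = x.size // x.shape[1]
        return self.gamma.reshape(sh) * xhat + self.beta.reshape(sh)

    def backward(self, grad):
        sh, axes = self._sh, self._axes
        xhat, inv, m = self._xhat, self._inv, self._m
        self.dgamma[...] = (grad * xhat).sum(axis=axes)
        self.dbeta[...] = grad.sum(axis=axes)
        g = grad * self.gamma.reshape(sh)
        gsum = g.sum(axis=axes).reshape(sh)
        gx = (g * xhat).sum(axis=axes).reshape(sh)
        return (inv.reshape(sh) / m) * (m * g - gsum - xhat * gx)

    def params(self):
        return [("gamma", self.gamma, self.dgamma), ("beta", self.beta, self.dbeta)]

    def state(self):
        return {
            "gamma": self.gamma,
            "beta": self.beta,
            "running_mean": self.running_mean,
            "running_var": self.running_var,
        }

    def load_state(self, state, prefix=""):
        self.gamma[...] = state[prefix + "gamma"]
        self.beta[...] = state[prefix + "beta"]
        self.running_mean[...] = state[prefix + "running_mean"]
        self.running_var[...] = state[prefix + "running_var"]


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, grad):
        return np.where(self._mask, grad, self.slope * grad)


class Sigmoid(Layer):
    def forward(self, x, training=False):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, grad):
        return grad * self._y * (1.0 - self._y)


class Dropout(Layer):
    """Inverted dropout; active only in training mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask.astype(F32)

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


def _im2col(x: np.ndarray, k: int, s: int, p: int):
    """(B, C, H, W) -> column matrix (B*Ho*Wo, C*k*k) plus geometry."""
    B, C, H, W = x.shape
    if p:
        x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    Hp, Wp = x.shape[2], x.shape[3]
    Ho = (Hp - k) // s + 1
    Wo = (Wp - k) // s + 1
    sb, sc, sh, sw = x.strides
    view = as_strided(
        x,
        shape=(B, C, k, k, Ho, Wo),
        strides=(sb, sc, sh, sw, sh * s, sw * s),
    )
    cols = view.transpose(0, 4, 5, 1, 2, 3).reshape(B * Ho * Wo, C * k * k)
    return np.ascontiguousarray(cols), (B, C, Hp, Wp, Ho, Wo)


def _col2im(cols: np.ndarray, geom, k: int, s: int, p: int):
    """Scatter-add inverse of :func:`_im2col`."""
    B, C, Hp, Wp, Ho, Wo = geom
    x = np.zeros((B, C, Hp, Wp), dtype=cols.dtype)
    cols6 = cols.reshape(B, Ho, Wo, C, k, k).transpose(0, 3, 4, 5, 1, 2)
    for i in range(k):
        for j in range(k):
            x[:, :, i : i + Ho * s : s, j : j + Wo * s : s] += cols6[:, :, i, j]
    if p:
        x = x[:, :, p:-p, p:-p]
    return x


class Conv2d(Layer):
    def __init__(self, c_in, c_out, k, stride, pad, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.W = (rng.standard_normal((c_in * k * k, c_out)) * scale).astype(F32)
        self.b = np.zeros(c_out, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.k, self.s, self.p = k, stride, pad
        self.c_in, self.c_out = c_in, c_out

    def forward(self, x, training=False):
        cols, geom = _im2col(x, self.k, self.s, self.p)
        self._cols, self._geom = cols, geom
        B, _, _, _, Ho, Wo = geom
        y = cols @ self.W + self.b
        return y.reshape(B, Ho, Wo, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, grad):
        B, C, Hp, Wp, Ho, Wo = self._geom
        g = grad.transpose(0, 2, 3, 1).reshape(-1, self.c_out)
        self.dW[...] = self._cols.T @ g
        self.db[...] = g.sum(axis=0)
        dcols = g @ self.W.T
        return _col2im(dcols, self._geom, self.k, self.s, self.p)

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]


class ConvTranspose2d(Layer):
    """Transposed convolution; output size (H-1)*s + k - 2p."""

    def __init__(self, c_in, c_out, k, stride, pad, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.W = (rng.standard_normal((c_in, c_out * k * k)) * scale).astype(F32)
        self.b = np.zeros(c_out, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.k, self.s, self.p = k, stride, pad
        self.c_in, self.c_out = c_in, c_out

    def forward(self, x, training=False):
        B, C, H, W = x.shape
        self._xmat = x.transpose(0, 2, 3, 1).reshape(-1, C)
        k, s, p = self.k, self.s, self.p
        Ho = (H - 1) * s + k - 2 * p
        Wo = (W - 1) * s + k - 2 * p
        cols = self._xmat @ self.W  # (B*H*W, c_out*k*k)
        geom = (B, self.c_out, Ho + 2 * p, Wo + 2 * p, H, W)
        self._geom_in = (B, H, W)
        y = _col2im(cols, geom, k, s, p)
        return y + self.b.reshape(1, -1, 1, 1)

    def backward(self, grad):
        B, H, W = self._geom_in
        cols, _ = _im2col(grad, self.k, self.s, self.p)
        self.dW[...] = self._xmat.T @ cols
        self.db[...] = grad.sum(axis=(0, 2, 3))
        dxmat = cols @ self.W.T
        return dxmat.reshape(B, H, W, self.c_in).transpose(0, 3, 1, 2)

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        out = []
        for i, layer in enumerate(self.layers):
            out.extend((f"{i}.{n}", p, g) for n, p, g in layer.params())
        return out

    def state(self):
        out = {}
        for i, layer in enumerate(self.layers):
            for n, v in layer.state().items():
                out[f"{i}.{n}"] = v
        return out

    def load_state(self, state, prefix=""):
        for i, layer in enumerate(self.layers):
            sub = {
                n[len(f"{prefix}{i}.") :]: v
                for n, v in state.items()
                if n.startswith(f"{prefix}{i}.")
            }
            layer.load_state(sub)


class Adam:
    """Adaptive-moments optimizer over a list of (name, param, grad) triples."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for _, p, _ in self.params]
        self.v = [np.zeros_like(p) for _, p, _ in self.params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for (name, p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# --- losses (value, gradient w.r.t. prediction) ----------------------------

def mse_loss(pred: np.ndarray, target: np.ndarray):
    diff = pred - target
    return float(np.mean(diff**2)), (2.0 / diff.size) * diff


def l1_loss(pred: np.ndarray, target: np.ndarray):
    diff = pred - target
    return float(np.mean(np.abs(diff))), np.sign(diff) / diff.size


def bce_loss(pred: np.ndarray, target: np.ndarray, eps: float = 1e-7):
    """Binary cross-entropy on probabilities (pred clamped away from 0/1)."""
    p = np.clip(pred, eps, 1.0 - eps)
    loss = float(np.mean(-(target * np.log(p) + (1 - target) * np.log(1 - p))))
    grad = (p - target) / (p * (1 - p)) / p.size
    grad = np.where((pred > eps) & (pred < 1 - eps), grad, 0.0)
    return loss, grad


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)
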