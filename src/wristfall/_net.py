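"""Minimal NumPy neural-network engine used by the classifier.

Implements exactly the layers the classifier architectures need — a
single-output LSTM, fully connected layers and batch normalisation — together
with backpropagation through time and an Adam optimizer.  Everything is
float32 and deterministic given a seed.
"""
from __future__ import annotations

import numpy as np

F32 = np.float32


def _sigmoid(z: np.ndarray) -> np.ndarray:
    # clipping keeps exp() finite in float32; saturation beyond |60| is exact 0/1
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60.0, 60.0)))


def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape).astype(F32)


class LSTM:
    """LSTM layer returning only its final hidden state.

    Gate order in the fused weight matrices is (input, forget, output, cell):
    the three sigmoid gates lead so one activation call covers them all.
    Accepts inputs of any sequence length.
    """

    param_names = ("Wx", "Wh", "b")
    trainable_names = ("Wx", "Wh", "b")

    def __init__(self, n_in: int, units: int, rng: np.random.Generator):
        self.n_in = n_in
        self.units = units
        self.Wx = _glorot(rng, (n_in, 4 * units))
        self.Wh = _glorot(rng, (units, 4 * units))
        b = np.zeros(4 * units, dtype=F32)
        b[units : 2 * units] = 1.0  # forget-gate bias
        self.b = b

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if x.ndim != 3 or x.shape[2] != self.n_in:
            raise ValueError(
                f"expected input of shape (batch, time, {self.n_in}), got {x.shape}"
            )
        B, T, _ = x.shape
        U = self.units
        h = np.zeros((B, U), dtype=F32)
        c = np.zeros((B, U), dtype=F32)
        # input contribution for every timestep in one matmul
        zx = (x.reshape(B * T, self.n_in) @ self.Wx).reshape(B, T, 4 * U)
        if training:
            self._x = x
            self._gates = np.empty((T, B, 4 * U), dtype=F32)
            self._c = np.empty((T, B, U), dtype=F32)
            self._h_prev = np.empty((T, B, U), dtype=F32)
        for t in range(T):
            z = zx[:, t, :] + h @ self.Wh + self.b
            sig = _sigmoid(z[:, : 3 * U])
            i = sig[:, :U]
            f = sig[:, U : 2 * U]
            o = sig[:, 2 * U :]
            g = np.tanh(z[:, 3 * U :])
            if training:
                self._h_prev[t] = h
            c_new = f * c + i * g
            h = o * np.tanh(c_new)
            if training:
                gt = self._gates[t]
                gt[:, : 3 * U] = sig
                gt[:, 3 * U :] = g
                self._c[t] = c_new
            c = c_new
        return h

    def backward(self, dh: np.ndarray) -> np.ndarray:
        x, gates = self._x, self._gates
        B, T, _ = x.shape
        U = self.units
        dz_all = np.empty((T, B, 4 * U), dtype=F32)
        dc = np.zeros((B, U), dtype=F32)
        dh = dh.astype(F32, copy=True)
        WhT = self.Wh.T
        for t in range(T - 1, -1, -1):
            gt = gates[t]
            sig = gt[:, : 3 * U]
            i = sig[:, :U]
            f = sig[:, U : 2 * U]
            o = sig[:, 2 * U :]
            g = gt[:, 3 * U :]
            c_prev = self._c[t - 1] if t > 0 else np.zeros((B, U), dtype=F32)
            tc = np.tanh(self._c[t])
            dc = dc + dh * o * (1.0 - tc * tc)
            dz = dz_all[t]
            dz[:, :U] = dc * g
            dz[:, U : 2 * U] = dc * c_prev
            dz[:, 2 * U : 3 * U] = dh * tc
            dz[:, : 3 * U] *= sig * (1.0 - sig)
            dz[:, 3 * U :] = (dc * i) * (1.0 - g * g)
            dh = dz @ WhT
            dc = dc * f
        # weight gradients as two large reductions over (time, batch)
        self.dWx = np.tensordot(x, dz_all, axes=((0, 1), (1, 0)))
        self.dWh = np.tensordot(self._h_prev, dz_all, axes=((0, 1), (0, 1)))
        self.db = dz_all.sum(axis=(0, 1))
        self._x = self._gates = self._c = self._h_prev = None
        return dh  # gradient w.r.t. inputs, unused upstream


class Dense:
    """Fully connected layer with optional rectifier activation."""

    param_names = ("W", "b")
    trainable_names = ("W", "b")

    def __init__(self, n_in: int, n_out: int, activation: str, rng: np.random.Generator):
        if activation not in ("relu", "linear"):
            raise ValueError("activation must be 'relu' or 'linear'")
        self.activation = activation
        self.W = _glorot(rng, (n_in, n_out))
        self.b = np.zeros(n_out, dtype=F32)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        z = x @ self.W + self.b
        if training:
            self._x = x
            self._z = z if self.activation == "relu" else None
        return np.maximum(z, 0.0) if self.activation == "relu" else z

    def backward(self, da: np.ndarray) -> np.ndarray:
        dz = da * (self._z > 0) if self.activation == "relu" else da
        self.dW = self._x.T @ dz
        self.db = dz.sum(axis=0)
        dx = dz @ self.W.T
        self._x = self._z = None
        return dx


class BatchNorm:
    """Batch normalisation over the feature axis of a (batch, features) input.

    ``running_mean``/``running_var`` are data statistics, not learned weights;
    they still count toward the parameter total and are serialized.
    """

    param_names = ("gamma", "beta", "running_mean", "running_var")
    trainable_names = ("gamma", "beta")

    # Momentum 0.9 lets the running statistics track the data within the
    # short training runs this package targets (a 0.99 default needs
    # thousands of updates before eval-mode inference matches training).
    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-3):
        self.momentum = momentum
        self.eps = eps
        self.gamma = np.ones(n_features, dtype=F32)
        self.beta = np.zeros(n_features, dtype=F32)
        self.running_mean = np.zeros(n_features, dtype=F32)
        self.running_var = np.ones(n_features, dtype=F32)
        self.update_running = True

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            if self.update_running:
                m = F32(self.momentum)
                self.running_mean = m * self.running_mean + (1 - m) * mean.astype(F32)
                self.running_var = m * self.running_var + (1 - m) * var.astype(F32)
            inv_std = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean) * inv_std
            self._xhat = xhat
            self._inv_std = inv_std
            return self.gamma * xhat + self.beta
        inv_std = 1.0 / np.sqrt(self.running_var + self.eps)
        return self.gamma * (x - self.running_mean) * inv_std + self.beta

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._xhat, self._inv_std
        B = dy.shape[0]
        self.dgamma = (dy * xhat).sum(axis=0)
        self.dbeta = dy.sum(axis=0)
        dx = (
            self.gamma
            * inv_std
            * (dy - dy.mean(axis=0) - xhat * (dy * xhat).mean(axis=0))
        )
        self._xhat = self._inv_std = None
        return dx.astype(F32)


class Adam:
    """Adam with the framework-default settings (lr 1e-3, 0.9/0.999)."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m: dict = {}
        self._v: dict = {}

    def step(self, layers, frozen_layers: frozenset = frozenset()) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1.0 - b2**self.t) / (1.0 - b1**self.t)
        for li, layer in enumerate(layers):
            if li in frozen_layers:
                continue
            for name in layer.trainable_names:
                grad = getattr(layer, "d" + name, None)
                if grad is None:
                    continue
                key = (li, name)
                m = self._m.get(key)
                if m is None:
                    m = np.zeros_like(grad)
                    self._v[key] = np.zeros_like(grad)
                v = self._v[key]
                m = b1 * m + (1 - b1) * grad
                v = b2 * v + (1 - b2) * grad * grad
                self._m[key], self._v[key] = m, v
                param = getattr(layer, name)
                param -= (lr_t * m / (np.sqrt(v) + self.eps)).astype(param.dtype)


def sigmoid(z: np.ndarray) -> np.ndarray:
    return _sigmoid(z)


def binary_cross_entropy(p: np.ndarray, y: np.ndarray, weights=None) -> float:
    p = np.clip(p, 1e-7, 1.0 - 1e-7)
    losses = -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    if weights is not None:
        losses = losses * weights
    return float(losses.mean())
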