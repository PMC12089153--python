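"""Compact CPU layer stack for 1-D convolutional classifiers.

Plain-numpy layers (1-D convolution via im2col + GEMM, batch normalization,
ReLU, pooling, linear) with hand-written backward passes, plus AdamW with
decoupled weight decay.  Sized for the small models this package trains:
single-CPU, float32, deterministic given a seed.
"""

from __future__ import annotations

import numpy as np

_F = np.float32


class Layer:
    """Base layer: ``params``/``grads``/``buffers`` are name->array dicts."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}
        self.training = True

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


class Conv1d(Layer):
    """1-D convolution over time, zero-padded to kernel//2 on both sides."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out, self.kernel, self.stride = c_in, c_out, kernel, stride
        self.pad = kernel // 2
        fan_in = c_in * kernel
        w = rng.standard_normal((c_out, c_in, kernel)) * np.sqrt(2.0 / fan_in)
        self.params = {"weight": w.astype(_F), "bias": np.zeros(c_out, dtype=_F)}

    def out_len(self, length: int) -> int:
        return (length + 2 * self.pad - self.kernel) // self.stride + 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, length = x.shape
        lout = self.out_len(length)
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=2)[:, :, :: self.stride, :]
        cols = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(b * lout, c * self.kernel)
        wmat = self.params["weight"].reshape(self.c_out, -1)
        out = cols @ wmat.T + self.params["bias"]
        self._cache = (cols, x.shape)
        return np.ascontiguousarray(out.reshape(b, lout, self.c_out).transpose(0, 2, 1))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, x_shape = self._cache
        b, c, length = x_shape
        lout = dout.shape[2]
        dmat = np.ascontiguousarray(dout.transpose(0, 2, 1)).reshape(b * lout, self.c_out)
        wmat = self.params["weight"].reshape(self.c_out, -1)
        self.grads["weight"] = (dmat.T @ cols).reshape(self.params["weight"].shape)
        self.grads["bias"] = dmat.sum(axis=0)
        dcols = (dmat @ wmat).reshape(b, lout, c, self.kernel).transpose(0, 2, 1, 3)
        dxp = np.zeros((b, c, length + 2 * self.pad), dtype=_F)
        for k in range(self.kernel):
            dxp[:, :, k : k + self.stride * lout : self.stride] += dcols[:, :, :, k]
        return dxp[:, :, self.pad : self.pad + length]


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, time)."""

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params = {"gamma": np.ones(c, dtype=_F), "beta": np.zeros(c, dtype=_F)}
        self.buffers = {"running_mean": np.zeros(c, dtype=_F), "running_var": np.ones(c, dtype=_F)}

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mu = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.buffers["running_mean"] = (
                (1 - self.momentum) * self.buffers["running_mean"] + self.momentum * mu
            ).astype(_F)
            self.buffers["running_var"] = (
                (1 - self.momentum) * self.buffers["running_var"] + self.momentum * var
            ).astype(_F)
        else:
            mu = self.buffers["running_mean"]
            var = self.buffers["running_var"]
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None]) * ivar[None, :, None]
        self._cache = (xhat, ivar)
        return self.params["gamma"][None, :, None] * xhat + self.params["beta"][None, :, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, ivar = self._cache
        n = dout.shape[0] * dout.shape[2]
        self.grads["gamma"] = (dout * xhat).sum(axis=(0, 2))
        self.grads["beta"] = dout.sum(axis=(0, 2))
        dxhat = dout * self.params["gamma"][None, :, None]
        if not self.training:
            return dxhat * ivar[None, :, None]
        term = (
            dxhat
            - dxhat.mean(axis=(0, 2), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2), keepdims=True)
        )
        return term * ivar[None, :, None]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class GlobalAveragePool(Layer):
    """Mean over time: [B, C, L] -> [B, C]."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._length = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.repeat(dout[:, :, None], self._length, axis=2) / self._length


class GlobalMaxPool(Layer):
    """Max over time (adaptive max pooling to one bin): [B, C, L] -> [B, C]."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._argmax = x.argmax(axis=2)
        self._shape = x.shape
        return x.max(axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = np.zeros(self._shape, dtype=_F)
        b, c, _ = self._shape
        bi, ci = np.meshgrid(np.arange(b), np.arange(c), indexing="ij")
        dx[bi, ci, self._argmax] = dout
        return dx


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        w = rng.standard_normal((d_out, d_in)) * np.sqrt(1.0 / d_in)
        self.params = {"weight": w.astype(_F), "bias": np.zeros(d_out, dtype=_F)}

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["weight"].T + self.params["bias"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["weight"] = dout.T @ self._x
        self.grads["bias"] = dout.sum(axis=0)
        return dout @ self.params["weight"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray, pos_weight: float = 1.0):
    """Binary cross-entropy from logits; returns (mean loss, dloss/dlogits)."""
    logits = np.asarray(logits, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.float64)
    # softplus(z) - y*z, numerically stable
    softplus = np.logaddexp(0.0, logits)
    w = np.where(targets > 0.5, pos_weight, 1.0)
    loss = float(np.mean(w * (softplus - targets * logits)))
    grad = w * (sigmoid(logits) - targets) / len(logits)
    return loss, grad


class AdamW:
    """Adam with decoupled weight decay over a named-parameter dict."""

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float,
        weight_decay: float = 0.1,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        frozen: set[str] | frozenset[str] = frozenset(),
    ):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.betas = betas
        self.eps = eps
        self.frozen = set(frozen)
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for name, p in self.params.items():
            if name in self.frozen or name not in grads:
                continue
            g = grads[name].astype(p.dtype)
            self.m[name] = b1 * self.m[name] + (1 - b1) * g
            self.v[name] = b2 * self.v[name] + (1 - b2) * g * g
            mhat = self.m[name] / bc1
            vhat = self.v[name] / bc2
            p -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p)


class ReduceLROnPlateau:
    """Halve (by ``factor``) the learning rate after ``patience`` epochs
    without improvement of the monitored quantity (lower is better)."""

    def __init__(self, optimizer: AdamW, patience: int = 10, factor: float = 0.5, min_lr: float = 1e-7):
        self.opt = optimizer
        self.patience = patience
        self.factor = factor
        self.min_lr = min_lr
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, metric: float) -> None:
        if metric < self.best - 1e-12:
            self.best = metric
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs > self.patience:
                self.opt.lr = max(self.min_lr, self.opt.lr * self.factor)
                self.bad_epochs = 0
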