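"""Compact neural-network core in pure numpy.

Provides exactly the pieces the two learning stages need: strided valid
2D/3D convolutions (sliding-window + einsum), ReLU, global average pooling,
a dense head, Adam, cosine-annealed learning rates, and binary
cross-entropy / mean-squared-error losses.  Everything is driven by a
single ``numpy.random.Generator``, so training is bit-reproducible for a
given seed on a given BLAS.

The networks used here are small (tens of thousands of parameters); the
point is a dependency-light, deterministic training loop, not scale.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class _ConvND(Layer):
    """Valid strided convolution over the last ``ndim`` axes.

    Input layout (N, C, *spatial); weight (F, C, *kernel).
    """

    ndim: int

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 rng: np.random.Generator):
        k = (kernel,) * self.ndim
        fan_in = c_in * kernel**self.ndim
        self.w = rng.normal(0.0, math.sqrt(2.0 / fan_in),
                            size=(c_out, c_in, *k)).astype(np.float64)
        self.b = np.zeros(c_out)
        self.stride = stride
        self.kernel = kernel

    def _windows(self, x):
        spatial_axes = tuple(range(2, 2 + self.ndim))
        win = sliding_window_view(x, (self.kernel,) * self.ndim, axis=spatial_axes)
        slicer = (slice(None), slice(None)) + (slice(None, None, self.stride),) * self.ndim
        return win[slicer]

    def forward(self, x, train):
        self._x_shape = x.shape
        win = self._windows(x)
        if train:
            self._win = win
        if self.ndim == 2:
            out = np.einsum("nchwij,fcij->nfhw", win, self.w, optimize=True)
        else:
            out = np.einsum("ncdhwijk,fcijk->nfdhw", win, self.w, optimize=True)
        out += self.b.reshape((1, -1) + (1,) * self.ndim)
        return out

    def backward(self, grad):
        spatial = tuple(range(2, 2 + self.ndim))
        self._db = grad.sum(axis=(0, *spatial))
        if self.ndim == 2:
            self._dw = np.einsum("nchwij,nfhw->fcij", self._win, grad, optimize=True)
        else:
            self._dw = np.einsum("ncdhwijk,nfdhw->fcijk", self._win, grad, optimize=True)
        del self._win
        dx = np.zeros(self._x_shape)
        s, k = self.stride, self.kernel
        out_spatial = grad.shape[2:]
        for offs in np.ndindex(*(k,) * self.ndim):
            wk = self.w[(slice(None), slice(None), *offs)]  # (F, C)
            contrib = np.einsum("nf...,fc->nc...", grad, wk, optimize=True)
            slicer = tuple(
                slice(o, o + s * d, s) for o, d in zip(offs, out_spatial)
            )
            dx[(slice(None), slice(None), *slicer)] += contrib
        return dx

    def params(self):
        return {"w": self.w, "b": self.b}

    def grads(self):
        return {"w": self._dw, "b": self._db}


class Conv2D(_ConvND):
    ndim = 2


class Conv3D(_ConvND):
    ndim = 3


class GlobalAvgPool(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.mean(axis=tuple(range(2, x.ndim)))

    def backward(self, grad):
        spatial = self._shape[2:]
        scale = 1.0 / np.prod(spatial)
        out = np.broadcast_to(
            grad.reshape(grad.shape + (1,) * len(spatial)), self._shape)
        return out * scale


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, math.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)

    def forward(self, x, train):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self._dw = self._x.T @ grad
        self._db = grad.sum(axis=0)
        return grad @ self.w.T

    def params(self):
        return {"w": self.w, "b": self.b}

    def grads(self):
        return {"w": self._dw, "b": self._db}


# ---------------------------------------------------------------------------


def cosine_annealing(lr0: float, epochs: int, eta_min_frac: float = 0.01,
                     restart_period: int | None = None) -> Callable[[int], float]:
    """Cosine-annealed learning rate by epoch; optional warm restarts."""
    eta_min = lr0 * eta_min_frac

    def lr(epoch: int) -> float:
        period = restart_period or epochs
        t = epoch % period if restart_period else min(epoch, epochs - 1)
        denom = max(period - 1, 1) if restart_period else max(epochs - 1, 1)
        return eta_min + 0.5 * (lr0 - eta_min) * (1 + math.cos(math.pi * t / denom))

    return lr


class Adam:
    def __init__(self, layers: Sequence[Layer], beta1=0.9, beta2=0.999, eps=1e-8):
        self.layers = [l for l in layers if l.params()]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [{k: np.zeros_like(v) for k, v in l.params().items()} for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params().items()} for l in self.layers]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for layer, m, v in zip(self.layers, self.m, self.v):
            g = layer.grads()
            p = layer.params()
            for k in p:
                m[k] = b1 * m[k] + (1 - b1) * g[k]
                v[k] = b2 * v[k] + (1 - b2) * g[k] ** 2
                mhat = m[k] / (1 - b1**self.t)
                vhat = v[k] / (1 - b2**self.t)
                p[k] -= lr * mhat / (np.sqrt(vhat) + self.eps)


def bce_with_logits(z: np.ndarray, y: np.ndarray,
                    positive_weight: float = 1.0) -> tuple[float, np.ndarray]:
    """Numerically stable binary cross-entropy on logits.

    ``positive_weight`` > 1 penalises missed positives more, shifting the
    trained operating point toward recall.
    """
    z, y = z.ravel(), y.ravel()
    w = np.where(y == 1, positive_weight, 1.0)
    loss = (np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))) * w
    p = 1.0 / (1.0 + np.exp(-z))
    return float(loss.mean()), (w * (p - y) / z.size).reshape(-1, 1)


def mse_loss(pred: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    pred, y = pred.ravel(), y.ravel()
    diff = pred - y
    return float((diff**2).mean()), (2.0 * diff / diff.size).reshape(-1, 1)


@dataclass
class TrainLog:
    epoch_losses: list[float]
    learning_rates: list[float]

    @property
    def final_loss(self) -> float:
        return self.epoch_losses[-1]


class Sequential:
    """A feed-forward stack with a seeded minibatch training loop."""

    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def predict(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        outs = [self.forward(x[i : i + batch_size]) for i in range(0, len(x), batch_size)]
        return np.concatenate(outs, axis=0)

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        *,
        epochs: int,
        batch_size: int,
        lr: float,
        seed: int,
        loss: Callable[[np.ndarray, np.ndarray], tuple[float, np.ndarray]],
        schedule: Callable[[int], float] | None = None,
        augment: Callable[[np.ndarray, np.random.Generator], np.ndarray] | None = None,
    ) -> TrainLog:
        rng = np.random.default_rng(seed)
        opt = Adam(self.layers)
        schedule = schedule or cosine_annealing(lr, epochs)
        losses, lrs = [], []
        n = len(x)
        for epoch in range(epochs):
            lr_e = schedule(epoch)
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                xb = x[idx]
                if augment is not None:
                    xb = augment(xb, rng)
                out = self.forward(xb, train=True)
                l, g = loss(out, y[idx])
                self.backward(g)
                opt.step(lr_e)
                epoch_loss += l * len(idx)
            losses.append(epoch_loss / n)
            lrs.append(lr_e)
        return TrainLog(losses, lrs)

    # -- persistence --------------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.params().items():
                out[f"layer{i}_{k}"] = v
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for k, v in layer.params().items():
                v[...] = arrays[f"layer{i}_{k}"]


def save_model(path: str | Path, net: Sequential, config: dict) -> None:
    """Single-file checkpoint: weights plus an embedded JSON config."""
    payload = dict(net.state_arrays())
    payload["_config_json"] = np.frombuffer(
        json.dumps(config).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **payload)


def load_model_config(path: str | Path) -> dict:
    with np.load(path) as z:
        return json.loads(bytes(z["_config_json"].tobytes()).decode())


def load_model_arrays(path: str | Path) -> dict[str, np.ndarray]:
    with np.load(path) as z:
        return {k: z[k] for k in z.files if k != "_config_json"}
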