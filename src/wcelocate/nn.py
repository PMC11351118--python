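"""Minimal NumPy neural-network engine.

Implements exactly the pieces the organ-localization model needs — strided
3x3/1x1 convolutions (im2col), ReLU, global average pooling, linear layers,
a stacked LSTM with full backpropagation-through-time, and the SGD-momentum,
Sharpness-Aware Minimization (SAM) and Adam optimizers.  Everything runs in
float32 on CPU and is deterministic given the initialization RNG and data
order.
"""

from __future__ import annotations

import copy
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2d",
    "ReLU",
    "GlobalAvgPool",
    "Linear",
    "Sequential",
    "LSTMStack",
    "softmax",
    "SGDMomentum",
    "Adam",
    "sam_perturb",
    "sam_restore",
    "clone_params",
    "params_equal",
]


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class Layer:
    """Base class: parameters and their gradients live in two dicts."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k in self.params:
            self.grads[k] = np.zeros_like(self.params[k])


class Conv2d(Layer):
    """2-D convolution with square kernel, stride and symmetric zero padding."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        stride: int = 1,
        pad: int = 0,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * kernel * kernel
        std = np.sqrt(2.0 / fan_in)
        self.params["W"] = rng.normal(0.0, std, (c_out, c_in, kernel, kernel)).astype(
            np.float32
        )
        self.params["b"] = np.zeros(c_out, dtype=np.float32)
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.zero_grad()
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k, s, p = self.kernel, self.stride, self.pad
        n, c, h, w = x.shape
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        oh = (x.shape[2] - k) // s + 1
        ow = (x.shape[3] - k) // s + 1
        win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        # [n, c, oh, ow, k, k] -> [n*oh*ow, c*k*k]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * k * k)
        cols = np.ascontiguousarray(cols, dtype=np.float32)
        wm = self.params["W"].reshape(-1, c * k * k).T
        out = cols @ wm + self.params["b"]
        out = out.reshape(n, oh, ow, -1).transpose(0, 3, 1, 2)
        if train:
            self._cache = (cols, x.shape, (n, oh, ow))
        return np.ascontiguousarray(out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, padded_shape, (n, oh, ow) = self._cache
        k, s, p = self.kernel, self.stride, self.pad
        c_out = dout.shape[1]
        dmat = dout.transpose(0, 2, 3, 1).reshape(n * oh * ow, c_out)
        self.grads["W"] += (dmat.T @ cols).reshape(self.params["W"].shape)
        self.grads["b"] += dmat.sum(axis=0)
        wm = self.params["W"].reshape(c_out, -1)
        dcols = (dmat @ wm).reshape(n, oh, ow, -1, k, k)
        c = padded_shape[1]
        dcols = dcols.reshape(n, oh, ow, c, k, k).transpose(0, 3, 1, 2, 4, 5)
        dx = np.zeros(padded_shape, dtype=np.float32)
        for ki in range(k):
            for kj in range(k):
                dx[:, :, ki : ki + s * oh : s, kj : kj + s * ow : s] += dcols[
                    :, :, :, :, ki, kj
                ]
        if p:
            dx = dx[:, :, p:-p, p:-p]
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class GlobalAvgPool(Layer):
    """[N, C, H, W] -> [N, C] spatial mean."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(
            dout[:, :, None, None] / (h * w), self._shape
        ).astype(np.float32)


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / d_in)
        self.params["W"] = rng.normal(0.0, std, (d_in, d_out)).astype(np.float32)
        self.params["b"] = np.zeros(d_out, dtype=np.float32)
        self.zero_grad()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        if x.ndim == 1:
            self.grads["W"] += np.outer(x, dout)
            self.grads["b"] += dout
        else:
            self.grads["W"] += x.T @ dout
            self.grads["b"] += dout.sum(axis=0)
        return dout @ self.params["W"].T


class Sequential:
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    __call__ = forward

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def param_items(self) -> list[tuple[Layer, str]]:
        return [(layer, k) for layer in self.layers for k in layer.params]


class LSTMStack(Layer):
    """``n_layers`` stacked LSTM layers processing a [T, d_in] sequence.

    Gate order in the packed weight matrices is (input, forget, cell, output);
    forget-gate biases start at 1.  ``forward`` returns the top layer's
    hidden states [T, hidden]; the output at step t depends only on inputs
    1..t (strict causality).
    """

    def __init__(
        self,
        d_in: int,
        hidden: int = 64,
        n_layers: int = 5,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.d_in, self.hidden, self.n_layers = d_in, hidden, n_layers
        for layer in range(n_layers):
            din = d_in if layer == 0 else hidden
            sx = np.sqrt(1.0 / din)
            sh = np.sqrt(1.0 / hidden)
            self.params[f"Wx{layer}"] = rng.normal(0, sx, (din, 4 * hidden)).astype(
                np.float32
            )
            self.params[f"Wh{layer}"] = rng.normal(0, sh, (hidden, 4 * hidden)).astype(
                np.float32
            )
            b = np.zeros(4 * hidden, dtype=np.float32)
            b[hidden : 2 * hidden] = 1.0  # forget gate bias
            self.params[f"b{layer}"] = b
        self.zero_grad()

    @staticmethod
    def _sigmoid(z: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-z))

    def forward(
        self,
        x: np.ndarray,
        h0: list[tuple[np.ndarray, np.ndarray]] | None = None,
        train: bool = False,
    ) -> tuple[np.ndarray, list[tuple[np.ndarray, np.ndarray]]]:
        """Returns (hidden states of top layer [T, hidden], final (h, c) per layer)."""
        T = x.shape[0]
        H = self.hidden
        if h0 is None:
            h0 = [
                (np.zeros(H, dtype=np.float32), np.zeros(H, dtype=np.float32))
                for _ in range(self.n_layers)
            ]
        seq = x.astype(np.float32)
        caches = []
        finals = []
        for layer in range(self.n_layers):
            Wx = self.params[f"Wx{layer}"]
            Wh = self.params[f"Wh{layer}"]
            b = self.params[f"b{layer}"]
            h, c = h0[layer]
            outs = np.empty((T, H), dtype=np.float32)
            steps = []
            for t in range(T):
                xt = seq[t]
                a = xt @ Wx + h @ Wh + b
                i = self._sigmoid(a[:H])
                f = self._sigmoid(a[H : 2 * H])
                g = np.tanh(a[2 * H : 3 * H])
                o = self._sigmoid(a[3 * H :])
                c_new = f * c + i * g
                tc = np.tanh(c_new)
                h_new = o * tc
                if train:
                    steps.append((xt, h, c, i, f, g, o, tc))
                h, c = h_new, c_new
                outs[t] = h
            caches.append(steps)
            finals.append((h, c))
            seq = outs
        if train:
            self._cache = caches
        return seq, finals

    def backward(self, dtop: np.ndarray) -> np.ndarray:
        """BPTT given the gradient w.r.t. the top layer's hidden states."""
        T = dtop.shape[0]
        H = self.hidden
        d_seq = dtop.astype(np.float32)
        for layer in range(self.n_layers - 1, -1, -1):
            steps = self._cache[layer]
            Wx = self.params[f"Wx{layer}"]
            Wh = self.params[f"Wh{layer}"]
            dWx = self.grads[f"Wx{layer}"]
            dWh = self.grads[f"Wh{layer}"]
            db = self.grads[f"b{layer}"]
            din = Wx.shape[0]
            dx_seq = np.zeros((T, din), dtype=np.float32)
            dh_next = np.zeros(H, dtype=np.float32)
            dc_next = np.zeros(H, dtype=np.float32)
            for t in range(T - 1, -1, -1):
                xt, h_prev, c_prev, i, f, g, o, tc = steps[t]
                dh = d_seq[t] + dh_next
                do = dh * tc
                dc = dh * o * (1.0 - tc * tc) + dc_next
                di = dc * g
                df = dc * c_prev
                dg = dc * i
                da = np.concatenate(
                    [
                        di * i * (1.0 - i),
                        df * f * (1.0 - f),
                        dg * (1.0 - g * g),
                        do * o * (1.0 - o),
                    ]
                )
                dWx += np.outer(xt, da)
                dWh += np.outer(h_prev, da)
                db += da
                dx_seq[t] = da @ Wx.T
                dh_next = da @ Wh.T
                dc_next = dc * f
            d_seq = dx_seq
        return d_seq

    def param_items(self) -> list[tuple["LSTMStack", str]]:
        return [(self, k) for k in self.params]


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------

ParamItems = Sequence[tuple[Layer, str]]


class SGDMomentum:
    def __init__(self, lr: float = 1e-3, momentum: float = 0.9):
        self.lr, self.momentum = lr, momentum
        self._v: dict[tuple[int, str], np.ndarray] = {}

    def step(self, items: ParamItems) -> None:
        for layer, k in items:
            key = (id(layer), k)
            v = self._v.get(key)
            if v is None:
                v = np.zeros_like(layer.params[k])
            v = self.momentum * v - self.lr * layer.grads[k]
            layer.params[k] += v
            self._v[key] = v


class Adam:
    def __init__(self, lr: float = 1e-3, b1: float = 0.9, b2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self._m: dict[tuple[int, str], np.ndarray] = {}
        self._v: dict[tuple[int, str], np.ndarray] = {}
        self._t = 0

    def step(self, items: ParamItems) -> None:
        self._t += 1
        b1, b2 = self.b1, self.b2
        for layer, k in items:
            key = (id(layer), k)
            g = layer.grads[k]
            m = self._m.get(key, np.zeros_like(g))
            v = self._v.get(key, np.zeros_like(g))
            m = b1 * m + (1 - b1) * g
            v = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self._t)
            vhat = v / (1 - b2**self._t)
            layer.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            self._m[key], self._v[key] = m, v


def _grad_norm(items: ParamItems) -> float:
    total = 0.0
    for layer, k in items:
        g = layer.grads[k]
        total += float((g.astype(np.float64) ** 2).sum())
    return float(np.sqrt(total))


def sam_perturb(items: ParamItems, rho: float) -> dict[tuple[int, str], np.ndarray]:
    """SAM ascent step: w += rho * g / ||g||; returns the perturbations so
    they can be undone before the descent update."""
    norm = _grad_norm(items) + 1e-12
    eps: dict[tuple[int, str], np.ndarray] = {}
    for layer, k in items:
        e = (rho / norm) * layer.grads[k]
        layer.params[k] += e
        eps[(id(layer), k)] = e
    return eps


def sam_restore(items: ParamItems, eps: dict[tuple[int, str], np.ndarray]) -> None:
    for layer, k in items:
        layer.params[k] -= eps[(id(layer), k)]


# ---------------------------------------------------------------------------
# parameter snapshots
# ---------------------------------------------------------------------------


def clone_params(items: ParamItems) -> list[np.ndarray]:
    return [layer.params[k].copy() for layer, k in items]


def restore_params(items: ParamItems, snapshot: list[np.ndarray]) -> None:
    for (layer, k), arr in zip(items, snapshot):
        layer.params[k] = arr.copy()


def params_equal(a: list[np.ndarray], b: list[np.ndarray]) -> bool:
    return len(a) == len(b) and all(
        x.shape == y.shape and np.array_equal(x, y) for x, y in zip(a, b)
    )
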