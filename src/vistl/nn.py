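"""Minimal NumPy neural-network library for timeline images.

Implements exactly the layers the three architectures need — 3x3 same
convolution (im2col + GEMM), max pooling, dense, ReLU, dropout and a GRU
with full backpropagation through time — plus Adam and a weighted
binary-cross-entropy loss. Everything is float32, seeded, and written so
that input gradients are available at any layer (required for Grad-CAM,
where the class-score gradient at the final convolutional layer flows back
through the recurrent head).

Gradient correctness is enforced by finite-difference checks in the test
suite rather than trusted by construction.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np

F32 = np.float32


class Layer:
    """Base layer: forward caches what backward needs; params/grads by name."""

    def __init__(self):
        self.params: Dict[str, np.ndarray] = {}
        self.grads: Dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """3x3 (configurable) same-padding convolution, stride 1."""

    def __init__(self, cin: int, cout: int, k: int = 3, rng: Optional[np.random.Generator] = None):
        super().__init__()
        self.cin, self.cout, self.k = cin, cout, k
        self.pad = k // 2
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / (cin * k * k))
        self.params["W"] = (rng.normal(0, scale, (cout, cin * k * k))).astype(F32)
        self.params["b"] = np.zeros(cout, dtype=F32)

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        N, C, H, W = x.shape
        p, k = self.pad, self.k
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        # (N, C, H, W, k, k) -> (N*H*W, C*k*k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(N * H * W, C * k * k)
        return np.ascontiguousarray(cols, dtype=F32)

    def forward(self, x, train=False):
        N, C, H, W = x.shape
        self._shape = (N, C, H, W)
        self._cols = self._im2col(x)
        y = self._cols @ self.params["W"].T + self.params["b"]
        return y.reshape(N, H, W, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dy):
        N, C, H, W = self._shape
        k, p = self.k, self.pad
        dy_flat = dy.transpose(0, 2, 3, 1).reshape(N * H * W, self.cout).astype(F32)
        self.grads["W"] = dy_flat.T @ self._cols
        self.grads["b"] = dy_flat.sum(axis=0)
        dcols = (dy_flat @ self.params["W"]).reshape(N, H, W, C, k, k)
        dxp = np.zeros((N, C, H + 2 * p, W + 2 * p), dtype=F32)
        for di in range(k):
            for dj in range(k):
                dxp[:, :, di:di + H, dj:dj + W] += dcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        return dxp[:, :, p:p + H, p:p + W]


class MaxPool2d(Layer):
    """Max pooling with independent factors per axis; trailing rows/cols
    that do not fill a window are cropped (gradient zero there)."""

    def __init__(self, ph: int, pw: int):
        super().__init__()
        self.ph, self.pw = ph, pw

    def forward(self, x, train=False):
        N, C, H, W = x.shape
        ph, pw = self.ph, self.pw
        H2, W2 = H // ph, W // pw
        self._in_shape = x.shape
        r = x[:, :, :H2 * ph, :W2 * pw].reshape(N, C, H2, ph, W2, pw)
        y = r.max(axis=(3, 5))
        # winner mask; exact float ties (rare) split the gradient
        self._r, self._y = r, y
        self._out_shape = (N, C, H2, W2)
        return y

    def backward(self, dy):
        N, C, H, W = self._in_shape
        ph, pw = self.ph, self.pw
        N_, C_, H2, W2 = self._out_shape
        win = (self._r == self._y[:, :, :, None, :, None])
        counts = win.sum(axis=(3, 5))
        dr = win * (dy / counts)[:, :, :, None, :, None]
        dx = np.zeros((N, C, H, W), dtype=F32)
        dx[:, :, :H2 * ph, :W2 * pw] = dr.reshape(N, C, H2 * ph, W2 * pw)
        return dx


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(F32)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0).astype(F32)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p, self.rng = p, rng

    def forward(self, x, train=False):
        if not train or self.p <= 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return (x * self._mask).astype(F32)

    def backward(self, dy):
        if self._mask is None:
            return dy
        return (dy * self._mask).astype(F32)


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class TimeFlatten(Layer):
    """(N, C, V, T) -> (N, T, C*V): per-time-step feature vectors."""

    def forward(self, x, train=False):
        self._shape = x.shape
        N, C, V, T = x.shape
        return np.ascontiguousarray(x.transpose(0, 3, 1, 2).reshape(N, T, C * V))

    def backward(self, dy):
        N, C, V, T = self._shape
        return np.ascontiguousarray(dy.reshape(N, T, C, V).transpose(0, 2, 3, 1))


class Transpose12(Layer):
    """(N, V, T) -> (N, T, V): image columns as a time sequence."""

    def forward(self, x, train=False):
        return np.ascontiguousarray(x.transpose(0, 2, 1))

    def backward(self, dy):
        return np.ascontiguousarray(dy.transpose(0, 2, 1))


class Dense(Layer):
    def __init__(self, din: int, dout: int, rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / din)
        self.params["W"] = rng.normal(0, scale, (din, dout)).astype(F32)
        self.params["b"] = np.zeros(dout, dtype=F32)

    def forward(self, x, train=False):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        dy = dy.astype(F32)
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class GRU(Layer):
    """Batch-first GRU with full BPTT.

    ``output`` is either the last hidden state or the mean of hidden states
    over time (stabler gradients for long sequences; still order-sensitive).
    """

    def __init__(self, din: int, dh: int, rng: Optional[np.random.Generator] = None,
                 output: str = "last"):
        super().__init__()
        rng = rng or np.random.default_rng()
        if output not in ("last", "mean"):
            raise ValueError("GRU output must be 'last' or 'mean'")
        self.output = output
        self.din, self.dh = din, dh
        sx = np.sqrt(1.0 / din)
        sh = np.sqrt(1.0 / dh)
        for g in ("z", "r", "n"):
            self.params[f"W{g}"] = rng.normal(0, sx, (din, dh)).astype(F32)
            self.params[f"U{g}"] = rng.normal(0, sh, (dh, dh)).astype(F32)
            self.params[f"b{g}"] = np.zeros(dh, dtype=F32)

    def forward(self, x, train=False):
        N, T, D = x.shape
        p = self.params
        h = np.zeros((N, self.dh), dtype=F32)
        self._x = x
        self._cache = []
        xz = x @ p["Wz"] + p["bz"]
        xr = x @ p["Wr"] + p["br"]
        xn = x @ p["Wn"] + p["bn"]
        hsum = np.zeros_like(h)
        for t in range(T):
            z = _sigmoid(xz[:, t] + h @ p["Uz"])
            r = _sigmoid(xr[:, t] + h @ p["Ur"])
            rh = r * h
            n = np.tanh(xn[:, t] + rh @ p["Un"])
            h_new = (1 - z) * n + z * h
            self._cache.append((h, z, r, n, rh))
            h = h_new.astype(F32)
            hsum += h
        self._hT = h
        return (hsum / T).astype(F32) if self.output == "mean" else h

    def backward(self, dout):
        x, p = self._x, self.params
        N, T, D = x.shape
        for k in self.params:
            self.grads[k] = np.zeros_like(self.params[k])
        g = self.grads
        dx = np.zeros_like(x)
        if self.output == "mean":
            dh = (dout / T).astype(F32)
        else:
            dh = dout.astype(F32)
        for t in range(T - 1, -1, -1):
            h_prev, z, r, n, rh = self._cache[t]
            dz = dh * (h_prev - n)
            dn = dh * (1 - z)
            dh_prev = dh * z
            dan = dn * (1 - n * n)
            g["Wn"] += x[:, t].T @ dan
            g["Un"] += rh.T @ dan
            g["bn"] += dan.sum(axis=0)
            drh = dan @ p["Un"].T
            dr = drh * h_prev
            dh_prev = dh_prev + drh * r
            dx[:, t] += dan @ p["Wn"].T
            daz = dz * z * (1 - z)
            g["Wz"] += x[:, t].T @ daz
            g["Uz"] += h_prev.T @ daz
            g["bz"] += daz.sum(axis=0)
            dh_prev = dh_prev + daz @ p["Uz"].T
            dx[:, t] += daz @ p["Wz"].T
            dar = dr * r * (1 - r)
            g["Wr"] += x[:, t].T @ dar
            g["Ur"] += h_prev.T @ dar
            g["br"] += dar.sum(axis=0)
            dh_prev = dh_prev + dar @ p["Ur"].T
            dx[:, t] += dar @ p["Wr"].T
            dh = dh_prev.astype(F32)
            if self.output == "mean" and t > 0:
                dh = dh + (dout / T).astype(F32)
        return dx


class Network:
    """Plain layer stack mapping (N, V, T) images to (N,) logits."""

    def __init__(self, layers: List[Layer], needs_channel_axis: bool = True):
        self.layers = layers
        self.needs_channel_axis = needs_channel_axis

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = x.astype(F32)
        if self.needs_channel_axis:
            h = h[:, None, :, :]
        for layer in self.layers:
            h = layer.forward(h, train=train)
        return h[:, 0]

    def backward(self, dlogit: np.ndarray, until: Optional[Layer] = None) -> np.ndarray:
        """Backprop from the logit; optionally stop after reaching ``until``
        (returns the gradient w.r.t. that layer's output)."""
        dy = dlogit[:, None].astype(F32)
        for layer in reversed(self.layers):
            if layer is until:
                return dy
            dy = layer.backward(dy)
        return dy

    def parameters(self):
        for i, layer in enumerate(self.layers):
            for name, val in layer.params.items():
                yield (i, name), layer

    def get_weights(self) -> Dict:
        return {(i, n): l.params[n].copy()
                for i, l in enumerate(self.layers) for n in l.params}

    def set_weights(self, weights: Dict) -> None:
        for (i, n), w in weights.items():
            self.layers[i].params[n] = w.copy()


class Adam:
    def __init__(self, net: Network, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m: Dict = {}
        self.v: Dict = {}
        self.t = 0

    def step(self):
        self.t += 1
        for i, layer in enumerate(self.net.layers):
            for name, p in layer.params.items():
                g = layer.grads.get(name)
                if g is None:
                    continue
                key = (i, name)
                m = self.m.setdefault(key, np.zeros_like(p))
                v = self.v.setdefault(key, np.zeros_like(p))
                m[:] = self.b1 * m + (1 - self.b1) * g
                v[:] = self.b2 * v + (1 - self.b2) * g * g
                mhat = m / (1 - self.b1 ** self.t)
                vhat = v / (1 - self.b2 ** self.t)
                p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(F32)


def weighted_bce_with_logits(logits: np.ndarray, y: np.ndarray,
                             weights: np.ndarray) -> Tuple[float, np.ndarray]:
    """Mean weighted BCE and its gradient w.r.t. the logits."""
    z = logits.astype(np.float64)
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    loss = float(np.mean(weights * loss))
    dlogit = (weights * (_sigmoid(z) - y)) / len(z)
    return loss, dlogit.astype(F32)
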