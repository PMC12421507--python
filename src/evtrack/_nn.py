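"""Minimal numpy CNN core for the dual-branch U-Net.

Convolutions are im2col + GEMM with hand-written backward passes; the whole
network is gradient-checked against numerical differentiation in the test
suite.  Everything is float32, batch-first (N, C, H, W), and deterministic
for a fixed seed in single-threaded mode.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_F32 = np.float32


# ------------------------------------------------------------------ layers


class Conv2d:
    """Same-padding k x k convolution (k odd)."""

    def __init__(self, rng: np.random.Generator, c_in: int, c_out: int, k: int = 3):
        fan_in = c_in * k * k
        self.W = (rng.standard_normal((c_out, c_in, k, k)) * np.sqrt(2.0 / fan_in)).astype(_F32)
        self.b = np.zeros(c_out, dtype=_F32)
        self.k = k
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))      # (N,C,H,W,k,k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
        cols = np.ascontiguousarray(cols, dtype=_F32)
        out = cols @ self.W.reshape(self.W.shape[0], -1).T + self.b
        self._cache = (cols, x.shape)
        return out.reshape(n, h, w, -1).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, xshape = self._cache
        n, c, h, w = xshape
        k, p = self.k, self.k // 2
        f = self.W.shape[0]
        dflat = dout.transpose(0, 2, 3, 1).reshape(n * h * w, f)
        self.dW = (dflat.T @ cols).reshape(self.W.shape)
        self.db = dflat.sum(axis=0)
        dcols = (dflat @ self.W.reshape(f, -1)).reshape(n, h, w, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=_F32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + h, j:j + w] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dxp[:, :, p:p + h, p:p + w] if p else dxp

    def params(self):
        return [(self, "W", "dW"), (self, "b", "db")]


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(_F32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0).astype(_F32)


class MaxPool2:
    """2x2 max pooling, stride 2; input H, W must be even."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        self._idx = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=_F32)
        np.put_along_axis(dxr, self._idx[..., None], dout[..., None].astype(_F32), axis=-1)
        dxr = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dxr.reshape(n, c, h, w)


class Upsample2:
    """Nearest-neighbour x2 upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5)).astype(_F32)


# ----------------------------------------------------------------- network


class DualUNet:
    """U-Net encoder/decoder with two 1x1 heads: a single-plane regression
    logit (distance map, squashed through a sigmoid downstream) and a
    3-plane classification logit (background / interior / border)."""

    def __init__(self, depth: int = 2, base_features: int = 16,
                 in_channels: int = 1, n_classes: int = 3, seed: int = 0):
        if depth < 2:
            raise ValueError("depth must be >= 2")
        if base_features < 8:
            raise ValueError("base_features must be >= 8")
        rng = np.random.default_rng(seed)
        self.depth = depth
        self.base_features = base_features
        self.in_channels = in_channels
        self.n_classes = n_classes

        feats = [base_features * 2 ** i for i in range(depth)]
        self.enc = []
        c_prev = in_channels
        for f in feats:
            self.enc.append([Conv2d(rng, c_prev, f), ReLU(), Conv2d(rng, f, f), ReLU()])
            c_prev = f
        self.pools = [MaxPool2() for _ in range(depth - 1)]
        self.ups = []
        self.dec = []
        for i in reversed(range(depth - 1)):
            self.ups.append((Upsample2(), Conv2d(rng, feats[i + 1], feats[i]), ReLU()))
            self.dec.append([Conv2d(rng, 2 * feats[i], feats[i]), ReLU(),
                             Conv2d(rng, feats[i], feats[i]), ReLU()])
        self.head_reg = Conv2d(rng, feats[0], 1, k=1)
        self.head_cls = Conv2d(rng, feats[0], n_classes, k=1)

    # -- plumbing

    def _layers(self):
        for blk in self.enc:
            yield from blk
        for up, conv, relu in self.ups:
            yield conv
        for blk in self.dec:
            yield from blk
        yield self.head_reg
        yield self.head_cls

    def params(self):
        out = []
        for layer in self._layers():
            if isinstance(layer, Conv2d):
                out.extend(layer.params())
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(l for l in self._layers() if isinstance(l, Conv2d)):
            out[f"conv{i}.W"] = layer.W
            out[f"conv{i}.b"] = layer.b
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        convs = [l for l in self._layers() if isinstance(l, Conv2d)]
        for i, layer in enumerate(convs):
            layer.W = state[f"conv{i}.W"].astype(_F32)
            layer.b = state[f"conv{i}.b"].astype(_F32)

    # -- forward / backward

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Returns (reg_logit (N,1,H,W), cls_logit (N,n_classes,H,W)).

        H and W must be divisible by 2**(depth-1).
        """
        x = np.ascontiguousarray(x, dtype=_F32)
        a = x
        skips = []
        for i, blk in enumerate(self.enc):
            for layer in blk:
                a = layer.forward(a)
            if i < self.depth - 1:
                skips.append(a)
                a = self.pools[i].forward(a)
        self._skip_channels = [s.shape[1] for s in skips]
        for (up, conv, relu), blk, skip in zip(self.ups, self.dec, reversed(skips)):
            a = relu.forward(conv.forward(up.forward(a)))
            a = np.concatenate([skip, a], axis=1)
            for layer in blk:
                a = layer.forward(a)
        return self.head_reg.forward(a), self.head_cls.forward(a)

    def backward(self, d_reg_logit: np.ndarray, d_cls_logit: np.ndarray) -> None:
        da = self.head_reg.backward(d_reg_logit) + self.head_cls.backward(d_cls_logit)
        dskips = []
        for (up, conv, relu), blk, c_skip in zip(reversed(self.ups), reversed(self.dec),
                                                 self._skip_channels):
            for layer in reversed(blk):
                da = layer.backward(da)
            dskip, da = da[:, :c_skip], da[:, c_skip:]
            dskips.append(dskip)
            da = up.backward(conv.backward(relu.backward(da)))
        for i in reversed(range(self.depth)):
            if i < self.depth - 1:
                da = self.pools[i].backward(da)
                da = da + dskips[i]
            for layer in reversed(self.enc[i]):
                da = layer.backward(da)


class Adam:
    """Adaptive-moment optimizer over the network's parameter list."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(getattr(obj, name)) for obj, name, _ in params]
        self.v = [np.zeros_like(getattr(obj, name)) for obj, name, _ in params]

    def step(self) -> None:
        self.t += 1
        for i, (obj, name, gname) in enumerate(self.params):
            g = getattr(obj, gname)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p = getattr(obj, name)
            setattr(obj, name, (p - self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(_F32))


# -------------------------------------------------------------- activations


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax_channels(z: np.ndarray) -> np.ndarray:
    """Per-pixel softmax over the channel axis of (N, C, H, W)."""
    zmax = z.max(axis=1, keepdims=True)
    e = np.exp(z - zmax)
    return e / e.sum(axis=1, keepdims=True)
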