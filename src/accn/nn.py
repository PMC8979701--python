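"""Minimal neural-network layer stack with hand-written backprop.

Everything here operates on NHWC float32 arrays. Each layer exposes
``forward(x) -> (y, cache)`` and ``backward(dy, cache) -> dx``; parameter
gradients are *accumulated* into ``Param.grad`` so that several forward
passes (labeled batch, raw unlabeled batch, strongly augmented batch) can
share one optimizer step. Caches are explicit, never stored on the layer,
so concurrent passes through the same network are safe.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "ReLU",
    "GlobalAvgPool",
    "Linear",
    "ResidualBlock",
    "Sequential",
    "Adam",
    "SGD",
    "build_backbone",
    "BACKBONES",
]


class Param:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy, cache):  # pragma: no cover - interface
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(N, H, W, C) -> (N, Ho, Wo, k*k*C) patch matrix (a view, then copy)."""
    n, h, w, c = x.shape
    ho = (h - k) // stride + 1
    wo = (w - k) // stride + 1
    sn, sh, sw, sc = x.strides
    view = as_strided(
        x,
        shape=(n, ho, wo, k, k, c),
        strides=(sn, sh * stride, sw * stride, sh, sw, sc),
        writeable=False,
    )
    return view.reshape(n, ho, wo, k * k * c)


class Conv2d(Layer):
    """k x k convolution, zero padding, He-normal init."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 k: int = 3, stride: int = 1):
        self.k, self.stride, self.c_in, self.c_out = k, stride, c_in, c_out
        self.pad = (k - 1) // 2
        fan_in = k * k * c_in
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, c_out))
        self.W = Param(w, "conv.W")
        self.b = Param(np.zeros(c_out), "conv.b")

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        p = self.pad
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        cols = _im2col(xp, self.k, self.stride)
        n, ho, wo, _ = cols.shape
        flat = cols.reshape(-1, cols.shape[-1])
        y = flat @ self.W.value + self.b.value
        return y.reshape(n, ho, wo, self.c_out), (flat, xp.shape, x.shape)

    def backward(self, dy, cache):
        flat, xp_shape, x_shape = cache
        n, ho, wo, _ = dy.shape
        dflat = dy.reshape(-1, self.c_out)
        self.W.grad += flat.T @ dflat
        self.b.grad += dflat.sum(axis=0)
        dcols = (dflat @ self.W.value.T).reshape(n, ho, wo, self.k, self.k, self.c_in)
        dxp = np.zeros(xp_shape, dtype=np.float32)
        s = self.stride
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, i:i + ho * s:s, j:j + wo * s:s, :] += dcols[:, :, :, i, j, :]
        p = self.pad
        if p:
            return dxp[:, p:-p, p:-p, :]
        return dxp


class ReLU(Layer):
    def forward(self, x):
        y = np.maximum(x, 0.0)
        return y, (x > 0.0)

    def backward(self, dy, cache):
        return dy * cache


class GlobalAvgPool(Layer):
    """(N, H, W, C) -> (N, C) mean over the spatial grid."""

    def forward(self, x):
        return x.mean(axis=(1, 2)), x.shape

    def backward(self, dy, cache):
        n, h, w, c = cache
        return np.broadcast_to(dy[:, None, None, :] / (h * w), cache).astype(np.float32)


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        w = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out))
        self.W = Param(w, "linear.W")
        self.b = Param(np.zeros(d_out), "linear.b")

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        return x @ self.W.value + self.b.value, x

    def backward(self, dy, cache):
        self.W.grad += cache.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


class ResidualBlock(Layer):
    """Two 3x3 convs with an identity (or 1x1 projection) skip connection."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, stride: int = 1):
        self.conv1 = Conv2d(c_in, c_out, rng, k=3, stride=stride)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(c_out, c_out, rng, k=3, stride=1)
        self.proj = None
        if stride != 1 or c_in != c_out:
            self.proj = Conv2d(c_in, c_out, rng, k=1, stride=stride)
        self.relu2 = ReLU()

    def params(self):
        ps = self.conv1.params() + self.conv2.params()
        if self.proj is not None:
            ps += self.proj.params()
        return ps

    def forward(self, x):
        h1, c1 = self.conv1.forward(x)
        a1, cr1 = self.relu1.forward(h1)
        h2, c2 = self.conv2.forward(a1)
        if self.proj is not None:
            skip, cp = self.proj.forward(x)
        else:
            skip, cp = x, None
        y, cr2 = self.relu2.forward(h2 + skip)
        return y, (c1, cr1, c2, cp, cr2)

    def backward(self, dy, cache):
        c1, cr1, c2, cp, cr2 = cache
        dsum = self.relu2.backward(dy, cr2)
        da1 = self.conv2.backward(dsum, c2)
        dh1 = self.relu1.backward(da1, cr1)
        dx = self.conv1.backward(dh1, c1)
        if self.proj is not None:
            dx = dx + self.proj.backward(dsum, cp)
        else:
            dx = dx + dsum
        return dx


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        out = []
        for lay in self.layers:
            out.extend(lay.params())
        return out

    def forward(self, x):
        caches = []
        for lay in self.layers:
            x, c = lay.forward(x)
            caches.append(c)
        return x, caches

    def backward(self, dy, caches):
        for lay, c in zip(reversed(self.layers), reversed(caches)):
            dy = lay.backward(dy, c)
        return dy


# ---------------------------------------------------------------------------
# Optimizers


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.eps = lr, eps
        self.b1, self.b2 = betas
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def state_dict(self):
        return {"t": self.t,
                "m": [a.copy() for a in self.m],
                "v": [a.copy() for a in self.v]}

    def load_state_dict(self, state):
        self.t = int(state["t"])
        for dst, src in zip(self.m, state["m"]):
            dst[...] = src
        for dst, src in zip(self.v, state["v"]):
            dst[...] = src


class SGD:
    def __init__(self, params: list[Param], lr: float = 1e-3, momentum: float = 0.9):
        self.params = params
        self.lr, self.momentum = lr, momentum
        self.vel = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        for p, v in zip(self.params, self.vel):
            v *= self.momentum
            v += p.grad
            p.value -= self.lr * v

    def state_dict(self):
        return {"t": self.t, "m": [a.copy() for a in self.vel], "v": []}

    def load_state_dict(self, state):
        self.t = int(state["t"])
        for dst, src in zip(self.vel, state["m"]):
            dst[...] = src


# ---------------------------------------------------------------------------
# Backbones (feature extractors G). Each factory returns (Sequential, d_f).


def _tiny_cnn(in_channels: int, widths, rng):
    """3-conv-block CNN; strided convs downsample, GAP gives d_f = widths[-1]."""
    w0, w1, w2 = widths
    layers = [
        Conv2d(in_channels, w0, rng, k=3, stride=2), ReLU(),
        Conv2d(w0, w1, rng, k=3, stride=2), ReLU(),
        Conv2d(w1, w2, rng, k=3, stride=1), ReLU(),
        GlobalAvgPool(),
    ]
    return Sequential(layers), w2


def _resnet_small(in_channels: int, widths, rng):
    """Small residual CNN: conv stem + two downsampling residual blocks."""
    w0, w1, w2 = widths
    layers = [
        Conv2d(in_channels, w0, rng, k=3, stride=1), ReLU(),
        ResidualBlock(w0, w1, rng, stride=2),
        ResidualBlock(w1, w2, rng, stride=2),
        GlobalAvgPool(),
    ]
    return Sequential(layers), w2


BACKBONES = {"tiny_cnn": _tiny_cnn, "resnet_small": _resnet_small}


def build_backbone(name: str, in_channels: int, widths, rng: np.random.Generator):
    if name not in BACKBONES:
        raise ValueError(f"unknown backbone {name!r}; available: {sorted(BACKBONES)}")
    widths = tuple(int(w) for w in widths)
    if len(widths) != 3 or any(w < 1 for w in widths):
        raise ValueError(f"widths must be 3 positive integers, got {widths}")
    return BACKBONES[name](in_channels, widths, rng)
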