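"""Minimal NumPy CNN layers with explicit forward/backward passes.

All tensors use NCHW layout and float32. Each layer caches whatever its
backward pass needs only when ``train=True`` is passed to ``forward``, so
pure inference over large rasters does not hold intermediate buffers.

Convolution is implemented by im2col (``sliding_window_view``) plus a BLAS
matmul; the col2im scatter in the backward pass iterates over kernel taps
(at most k*k slice-adds) instead of per-pixel indexing.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A learnable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad", "state")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.state: dict = {}  # optimizer slots (e.g. Adam moments)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    """Base class: forward(x, train) -> y, backward(dy) -> dx."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def same_padding(kernel: int, dilation: int = 1) -> int:
    """Padding that preserves spatial size for stride-1 convolution.

    Solves the dilated-convolution output-size relation for out == in:
    padding = dilation * (kernel - 1) / 2 (odd kernels only).
    """
    if kernel % 2 == 0:
        raise ValueError("same padding requires an odd kernel")
    return dilation * (kernel - 1) // 2


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, dilation: int):
    """Return patch matrix of shape (N, Ho, Wo, C, kh, kw) as a view."""
    eh = dilation * (kh - 1) + 1
    ew = dilation * (kw - 1) + 1
    win = sliding_window_view(x, (eh, ew), axis=(2, 3))
    return win[:, :, ::stride, ::stride, ::dilation, ::dilation].transpose(
        0, 2, 3, 1, 4, 5
    )


class Conv2d(Layer):
    """2-D convolution with stride and dilation, He-initialised."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        stride: int = 1,
        padding: int = 0,
        dilation: int = 1,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ):
        rng = rng if rng is not None else np.random.default_rng()
        fan_in = in_channels * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_channels, in_channels, kernel, kernel))
        self.weight = Param(w)
        self.bias = Param(np.zeros(out_channels)) if bias else None
        self.kernel, self.stride, self.padding, self.dilation = kernel, stride, padding, dilation
        self.in_channels, self.out_channels = in_channels, out_channels
        self._cache = None

    def params(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x, train: bool = False):
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {x.shape[1]}"
            )
        p = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        col = _im2col(xp, self.kernel, self.kernel, self.stride, self.dilation)
        n, ho, wo = col.shape[:3]
        col2 = np.ascontiguousarray(col).reshape(n * ho * wo, -1)
        wmat = self.weight.value.reshape(self.out_channels, -1)
        out = col2 @ wmat.T
        if self.bias is not None:
            out += self.bias.value
        out = out.reshape(n, ho, wo, self.out_channels).transpose(0, 3, 1, 2)
        if train:
            self._cache = (col2, x.shape, xp.shape, ho, wo)
        return np.ascontiguousarray(out)

    def backward(self, dy):
        col2, xshape, xpshape, ho, wo = self._cache
        n = xshape[0]
        dyf = dy.transpose(0, 2, 3, 1).reshape(n * ho * wo, self.out_channels)
        self.weight.grad += (dyf.T @ col2).reshape(self.weight.value.shape)
        if self.bias is not None:
            self.bias.grad += dyf.sum(axis=0)
        wmat = self.weight.value.reshape(self.out_channels, -1)
        dcol = (dyf @ wmat).reshape(n, ho, wo, self.in_channels, self.kernel, self.kernel)
        dcol = dcol.transpose(0, 3, 1, 2, 4, 5)  # N,C,Ho,Wo,kh,kw
        dxp = np.zeros(xpshape, dtype=np.float32)
        s, d = self.stride, self.dilation
        for i in range(self.kernel):
            for j in range(self.kernel):
                dxp[:, :, i * d : i * d + ho * s : s, j * d : j * d + wo * s : s] += dcol[
                    :, :, :, :, i, j
                ]
        p = self.padding
        self._cache = None
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class BatchNorm2d(Layer):
    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train: bool = False):
        c = x.shape[1]
        g = self.gamma.value.reshape(1, c, 1, 1)
        b = self.beta.value.reshape(1, c, 1, 1)
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean.reshape(1, c, 1, 1)) * inv.reshape(1, c, 1, 1)
            self._cache = (xhat, inv)
            return (g * xhat + b).astype(np.float32)
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        xhat = (x - self.running_mean.reshape(1, c, 1, 1)) * inv.reshape(1, c, 1, 1)
        return (g * xhat + b).astype(np.float32)

    def backward(self, dy):
        xhat, inv = self._cache
        self._cache = None
        n, c, h, w = dy.shape
        m = n * h * w
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.value.reshape(1, c, 1, 1)
        dxhat = dy * g
        # standard batch-norm backward, reduced over N,H,W per channel
        t1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        t2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (inv.reshape(1, c, 1, 1) / m) * (m * dxhat - t1 - xhat * t2)


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, train: bool = False):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy):
        dx = dy * self._mask
        self._mask = None
        return dx


class MaxPool2d(Layer):
    def __init__(self, kernel: int = 3, stride: int = 2, padding: int = 1):
        self.kernel, self.stride, self.padding = kernel, stride, padding
        self._cache = None

    def forward(self, x, train: bool = False):
        p = self.padding
        xp = (
            np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
            if p
            else x
        )
        win = sliding_window_view(xp, (self.kernel, self.kernel), axis=(2, 3))
        win = win[:, :, :: self.stride, :: self.stride]
        n, c, ho, wo = win.shape[:4]
        flat = win.reshape(n, c, ho, wo, -1)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, x.shape, xp.shape, ho, wo)
        return np.ascontiguousarray(out)

    def backward(self, dy):
        idx, xshape, xpshape, ho, wo = self._cache
        self._cache = None
        dxp = np.zeros(xpshape, dtype=np.float32)
        s = self.stride
        for i in range(self.kernel):
            for j in range(self.kernel):
                mask = idx == i * self.kernel + j
                dxp[:, :, i : i + ho * s : s, j : j + wo * s : s] += dy * mask
        p = self.padding
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


def _linear_interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Dense (n_out, n_in) matrix of 1-D linear interpolation weights.

    Uses the half-pixel-center convention: source coordinate of output o is
    (o + 0.5) * n_in / n_out - 0.5, clamped to the valid range.
    """
    m = np.zeros((n_out, n_in), dtype=np.float32)
    scale = n_in / n_out
    for o in range(n_out):
        src = (o + 0.5) * scale - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        i0 = int(np.floor(src))
        i1 = min(i0 + 1, n_in - 1)
        w1 = src - i0
        m[o, i0] += 1.0 - w1
        m[o, i1] += w1
    return m


class BilinearUpsample(Layer):
    """Scale-factor bilinear upsampling as two separable linear maps."""

    def __init__(self, scale: int):
        self.scale = scale
        self._mats: dict[tuple[int, int], np.ndarray] = {}
        self._in_hw = None

    def _mat(self, n_in: int) -> np.ndarray:
        key = (n_in, self.scale)
        if key not in self._mats:
            self._mats[key] = _linear_interp_matrix(n_in * self.scale, n_in)
        return self._mats[key]

    def forward(self, x, train: bool = False):
        h, w = x.shape[2:]
        mh, mw = self._mat(h), self._mat(w)
        if train:
            self._in_hw = (h, w)
        y = np.einsum("oh,nchw->ncow", mh, x, optimize=True)
        return np.einsum("pw,ncow->ncop", mw, y, optimize=True).astype(np.float32)

    def backward(self, dy):
        h, w = self._in_hw
        self._in_hw = None
        mh, mw = self._mat(h), self._mat(w)
        d = np.einsum("pw,ncop->ncow", mw, dy, optimize=True)
        return np.einsum("oh,ncow->nchw", mh, d, optimize=True).astype(np.float32)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train: bool = False):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


def conv_bn_relu(
    in_ch: int,
    out_ch: int,
    kernel: int = 3,
    stride: int = 1,
    dilation: int = 1,
    rng: np.random.Generator | None = None,
) -> Sequential:
    """Conv (same padding at stride 1) + batch norm + ReLU."""
    pad = same_padding(kernel, dilation) if kernel % 2 == 1 else 0
    return Sequential(
        Conv2d(in_ch, out_ch, kernel, stride=stride, padding=pad, dilation=dilation,
               bias=False, rng=rng),
        BatchNorm2d(out_ch),
        ReLU(),
    )


class ResidualBlock(Layer):
    """Basic two-conv residual unit with optional projection shortcut."""

    def __init__(self, in_ch: int, out_ch: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        last_bn = BatchNorm2d(out_ch)
        # zero-init the residual branch's final scale so each block starts
        # as (a projection of) the identity; stabilises from-scratch training
        last_bn.gamma.value[...] = 0.0
        self.main = Sequential(
            Conv2d(in_ch, out_ch, 3, stride=stride, padding=1, bias=False, rng=rng),
            BatchNorm2d(out_ch),
            ReLU(),
            Conv2d(out_ch, out_ch, 3, stride=1, padding=1, bias=False, rng=rng),
            last_bn,
        )
        if stride != 1 or in_ch != out_ch:
            self.shortcut: Layer | None = Sequential(
                Conv2d(in_ch, out_ch, 1, stride=stride, bias=False, rng=rng),
                BatchNorm2d(out_ch),
            )
        else:
            self.shortcut = None
        self._mask = None

    def params(self):
        ps = self.main.params()
        if self.shortcut is not None:
            ps += self.shortcut.params()
        return ps

    def forward(self, x, train: bool = False):
        y = self.main.forward(x, train=train)
        s = x if self.shortcut is None else self.shortcut.forward(x, train=train)
        out = y + s
        if train:
            self._mask = out > 0
        return np.maximum(out, 0.0)

    def backward(self, dy):
        d = dy * self._mask
        self._mask = None
        dx = self.main.backward(d)
        if self.shortcut is None:
            dx = dx + d
        else:
            dx = dx + self.shortcut.backward(d)
        return dx


def iter_layers(root) -> "list[Layer]":
    """All Layer instances reachable from ``root`` (including itself)."""
    seen: list[Layer] = []

    def walk(obj):
        if isinstance(obj, Layer):
            if any(obj is s for s in seen):
                return
            seen.append(obj)
            for v in vars(obj).values():
                walk(v)
        elif isinstance(obj, (list, tuple)):
            for v in obj:
                walk(v)

    walk(root)
    return seen


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    """Stable softmax over the channel axis of an NCHW tensor."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)
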