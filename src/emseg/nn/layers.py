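"""Layer implementations (numpy, channel-first single-sample tensors).

Convolutions use im2col + matmul; backward passes are exact analytic
gradients (verified against finite differences in the test suite).
Padding semantics follow the TensorFlow convention: ``"same"`` pads
asymmetrically so that the output size is ``ceil(in / stride)``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

from .graph import Layer

__all__ = [
    "Conv2D", "DepthwiseConv2D", "BatchNorm", "Activation", "MaxPool2D",
    "AvgPool2D", "GlobalAvgPool", "UpSampling2D", "Concatenate", "Add",
    "Multiply", "ZeroPadding2D",
]


def _pair(v) -> tuple[int, int]:
    if isinstance(v, (tuple, list)):
        return int(v[0]), int(v[1])
    return int(v), int(v)


def _same_pad(size: int, k: int, s: int) -> tuple[int, int]:
    out = -(-size // s)
    total = max((out - 1) * s + k - size, 0)
    return total // 2, total - total // 2


def _pad_amounts(shape: tuple[int, int], k: tuple[int, int], s: tuple[int, int],
                 padding) -> tuple[tuple[int, int], tuple[int, int]]:
    if padding == "same":
        return _same_pad(shape[0], k[0], s[0]), _same_pad(shape[1], k[1], s[1])
    if padding == "valid":
        return (0, 0), (0, 0)
    ph, pw = _pair(padding)
    return (ph, ph), (pw, pw)


def _windows(xp: np.ndarray, k: tuple[int, int], s: tuple[int, int]) -> np.ndarray:
    """View of shape (C, kh, kw, OH, OW) over the padded array ``xp``."""
    c, h, w = xp.shape
    oh = (h - k[0]) // s[0] + 1
    ow = (w - k[1]) // s[1] + 1
    sc, sh, sw = xp.strides
    return as_strided(xp, (c, k[0], k[1], oh, ow),
                      (sc, sh, sw, sh * s[0], sw * s[1]), writeable=False)


class Conv2D(Layer):
    """2-D convolution (optionally grouped), He-normal initialized."""

    def __init__(self, filters: int, kernel_size, strides=1, padding="same",
                 use_bias: bool = True, groups: int = 1, name=None,
                 rng: np.random.Generator | None = None):
        super().__init__(name)
        self.filters = int(filters)
        self.k = _pair(kernel_size)
        self.s = _pair(strides)
        self.padding = padding
        self.use_bias = use_bias
        self.groups = int(groups)
        self.rng = rng

    def build(self, in_channels: list[int]) -> None:
        cin = in_channels[0]
        if cin % self.groups or self.filters % self.groups:
            raise ValueError("channels not divisible by groups")
        fan_in = (cin // self.groups) * self.k[0] * self.k[1]
        rng = self.rng or np.random.default_rng(0)
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       (self.filters, cin // self.groups, *self.k))
        self.w = self.add_param("kernel", w)
        self.b = self.add_param("bias", np.zeros(self.filters)) if self.use_bias else None

    def out_channels(self, in_channels):
        return self.filters

    def forward(self, xs, training, cache):
        x = xs[0]
        (pt, pb), (pl, pr) = _pad_amounts(x.shape[1:], self.k, self.s, self.padding)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr)))
        win = _windows(xp, self.k, self.s)
        c, kh, kw, oh, ow = win.shape
        g = self.groups
        if g == 1:
            cols = win.reshape(c * kh * kw, oh * ow)
            wmat = self.w.value.reshape(self.filters, -1)
            out = wmat @ cols
            out = out.reshape(self.filters, oh, ow)
        else:
            cpg, fpg = c // g, self.filters // g
            out = np.empty((self.filters, oh, ow), np.float32)
            for gi in range(g):
                sub = win[gi * cpg:(gi + 1) * cpg].reshape(cpg * kh * kw, oh * ow)
                wmat = self.w.value[gi * fpg:(gi + 1) * fpg].reshape(fpg, -1)
                out[gi * fpg:(gi + 1) * fpg] = (wmat @ sub).reshape(fpg, oh, ow)
        if self.b is not None:
            out += self.b.value[:, None, None]
        cache.update(xp_shape=xp.shape, pads=(pt, pb, pl, pr), x_shape=x.shape,
                     win=win)
        return out

    def backward(self, grad, cache):
        if self.groups != 1:
            raise NotImplementedError("backward for grouped conv is limited to groups=1")
        kh, kw = self.k
        sh, sw = self.s
        f, oh, ow = grad.shape
        win = cache["win"]
        cols = win.reshape(win.shape[0] * kh * kw, oh * ow)
        gflat = grad.reshape(f, -1)
        gw = (gflat @ cols.T).reshape(self.w.value.shape)
        self.w.grad = gw if self.w.grad is None else self.w.grad + gw
        if self.b is not None:
            gb = grad.sum(axis=(1, 2))
            self.b.grad = gb if self.b.grad is None else self.b.grad + gb
        wmat = self.w.value.reshape(f, -1)
        dcols = (wmat.T @ gflat).reshape(win.shape)
        dxp = np.zeros(cache["xp_shape"], np.float32)
        for i in range(kh):
            for j in range(kw):
                dxp[:, i:i + sh * (oh - 1) + 1:sh, j:j + sw * (ow - 1) + 1:sw] += dcols[:, i, j]
        pt, pb, pl, pr = cache["pads"]
        _, h, w = cache["x_shape"]
        return [dxp[:, pt:pt + h, pl:pl + w]]


class DepthwiseConv2D(Conv2D):
    """Per-channel convolution with depth multiplier 1."""

    def __init__(self, kernel_size, strides=1, padding="same", use_bias=False,
                 name=None, rng=None):
        super().__init__(filters=0, kernel_size=kernel_size, strides=strides,
                         padding=padding, use_bias=use_bias, groups=0, name=name,
                         rng=rng)

    def build(self, in_channels):
        cin = in_channels[0]
        self.filters = cin
        self.groups = cin
        fan_in = self.k[0] * self.k[1]
        rng = self.rng or np.random.default_rng(0)
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (cin, 1, *self.k))
        self.w = self.add_param("kernel", w)
        self.b = self.add_param("bias", np.zeros(cin)) if self.use_bias else None

    def out_channels(self, in_channels):
        return in_channels[0]

    def forward(self, xs, training, cache):
        x = xs[0]
        (pt, pb), (pl, pr) = _pad_amounts(x.shape[1:], self.k, self.s, self.padding)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr)))
        win = _windows(xp, self.k, self.s)
        out = np.einsum("ckl...,ckl->c...", win, self.w.value[:, 0], optimize=True)
        if self.b is not None:
            out = out + self.b.value[:, None, None]
        cache.update(win=win, xp_shape=xp.shape, pads=(pt, pb, pl, pr),
                     x_shape=x.shape)
        return np.ascontiguousarray(out, np.float32)

    def backward(self, grad, cache):
        kh, kw = self.k
        sh, sw = self.s
        c, oh, ow = grad.shape
        win = cache["win"]
        gw = np.einsum("cklij,cij->ckl", win, grad, optimize=True)[:, None]
        self.w.grad = gw if self.w.grad is None else self.w.grad + gw
        if self.b is not None:
            gb = grad.sum(axis=(1, 2))
            self.b.grad = gb if self.b.grad is None else self.b.grad + gb
        dxp = np.zeros(cache["xp_shape"], np.float32)
        for i in range(kh):
            for j in range(kw):
                dxp[:, i:i + sh * (oh - 1) + 1:sh, j:j + sw * (ow - 1) + 1:sw] += \
                    self.w.value[:, 0, i, j][:, None, None] * grad
        pt, pb, pl, pr = cache["pads"]
        _, h, w = cache["x_shape"]
        return [dxp[:, pt:pt + h, pl:pl + w]]


class BatchNorm(Layer):
    """Channelwise batch normalization (statistics over H, W for batch-of-one).

    ``scale=False`` drops the gamma parameter (as some classification stems
    do); moving mean/variance are non-trainable parameters so that they are
    serialized and counted like any framework would.
    """

    def __init__(self, eps: float = 1e-3, momentum: float = 0.99,
                 scale: bool = True, name=None):
        super().__init__(name)
        self.eps = eps
        self.momentum = momentum
        self.scale = scale

    def build(self, in_channels):
        c = in_channels[0]
        self.gamma = self.add_param("gamma", np.ones(c)) if self.scale else None
        self.beta = self.add_param("beta", np.zeros(c))
        self.mmean = self.add_param("moving_mean", np.zeros(c), trainable=False)
        self.mvar = self.add_param("moving_variance", np.ones(c), trainable=False)

    def forward(self, xs, training, cache):
        x = xs[0]
        if training:
            mean = x.mean(axis=(1, 2))
            var = x.var(axis=(1, 2))
            self.mmean.value = (self.momentum * self.mmean.value
                                + (1 - self.momentum) * mean).astype(np.float32)
            self.mvar.value = (self.momentum * self.mvar.value
                               + (1 - self.momentum) * var).astype(np.float32)
        else:
            mean, var = self.mmean.value, self.mvar.value
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * inv[:, None, None]
        g = self.gamma.value if self.gamma is not None else 1.0
        out = xhat * (g[:, None, None] if self.gamma is not None else 1.0) \
            + self.beta.value[:, None, None]
        cache.update(xhat=xhat, inv=inv, training=training)
        return out.astype(np.float32)

    def backward(self, grad, cache):
        xhat, inv = cache["xhat"], cache["inv"]
        g = self.gamma.value if self.gamma is not None else np.ones(grad.shape[0],
                                                                    np.float32)
        gb = grad.sum(axis=(1, 2))
        self.beta.grad = gb if self.beta.grad is None else self.beta.grad + gb
        if self.gamma is not None:
            gg = (grad * xhat).sum(axis=(1, 2))
            self.gamma.grad = gg if self.gamma.grad is None else self.gamma.grad + gg
        gx_hat = grad * g[:, None, None]
        if not cache["training"]:
            return [gx_hat * inv[:, None, None]]
        n = grad.shape[1] * grad.shape[2]
        sum_g = gx_hat.sum(axis=(1, 2), keepdims=True)
        sum_gx = (gx_hat * xhat).sum(axis=(1, 2), keepdims=True)
        dx = (gx_hat - sum_g / n - xhat * sum_gx / n) * inv[:, None, None]
        return [dx.astype(np.float32)]


class Activation(Layer):
    """Pointwise nonlinearity: relu, sigmoid, swish, linear or softmax
    (softmax acts across the channel axis, per pixel)."""

    def __init__(self, kind: str, name=None):
        super().__init__(name)
        if kind not in {"relu", "sigmoid", "swish", "softmax", "linear"}:
            raise ValueError(f"unknown activation {kind!r}")
        self.kind = kind

    def forward(self, xs, training, cache):
        x = xs[0]
        if self.kind == "relu":
            out = np.maximum(x, 0.0)
        elif self.kind == "sigmoid":
            out = 1.0 / (1.0 + np.exp(-x))
        elif self.kind == "swish":
            sig = 1.0 / (1.0 + np.exp(-x))
            out = x * sig
            cache["sig"] = sig
        elif self.kind == "softmax":
            z = x - x.max(axis=0, keepdims=True)
            e = np.exp(z)
            out = e / e.sum(axis=0, keepdims=True)
        else:
            out = x
        cache["x"], cache["out"] = x, out
        return out.astype(np.float32)

    def backward(self, grad, cache):
        x, out = cache["x"], cache["out"]
        if self.kind == "relu":
            return [grad * (x > 0)]
        if self.kind == "sigmoid":
            return [grad * out * (1.0 - out)]
        if self.kind == "swish":
            sig = cache["sig"]
            return [grad * (sig + x * sig * (1.0 - sig))]
        if self.kind == "softmax":
            dot = (grad * out).sum(axis=0, keepdims=True)
            return [out * (grad - dot)]
        return [grad]


class MaxPool2D(Layer):
    def __init__(self, pool_size=2, strides=None, padding="valid", name=None):
        super().__init__(name)
        self.k = _pair(pool_size)
        self.s = _pair(strides) if strides is not None else self.k
        self.padding = padding

    def forward(self, xs, training, cache):
        x = xs[0]
        (pt, pb), (pl, pr) = _pad_amounts(x.shape[1:], self.k, self.s, self.padding)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr)), constant_values=-np.inf)
        win = _windows(xp, self.k, self.s)
        c, kh, kw, oh, ow = win.shape
        flat = win.reshape(c, kh * kw, oh, ow)
        arg = flat.argmax(axis=1)
        out = np.take_along_axis(flat, arg[:, None], axis=1)[:, 0]
        cache.update(arg=arg, xp_shape=xp.shape, pads=(pt, pb, pl, pr),
                     x_shape=x.shape, oshape=(oh, ow))
        return np.ascontiguousarray(out, np.float32)

    def backward(self, grad, cache):
        kh, kw = self.k
        sh, sw = self.s
        oh, ow = cache["oshape"]
        arg = cache["arg"]
        dxp = np.zeros(cache["xp_shape"], np.float32)
        for idx in range(kh * kw):
            i, j = divmod(idx, kw)
            m = arg == idx
            if not m.any():
                continue
            dxp[:, i:i + sh * (oh - 1) + 1:sh, j:j + sw * (ow - 1) + 1:sw] += grad * m
        pt, pb, pl, pr = cache["pads"]
        _, h, w = cache["x_shape"]
        return [dxp[:, pt:pt + h, pl:pl + w]]


class AvgPool2D(Layer):
    def __init__(self, pool_size=2, strides=None, padding="valid", name=None):
        super().__init__(name)
        self.k = _pair(pool_size)
        self.s = _pair(strides) if strides is not None else self.k
        self.padding = padding

    def forward(self, xs, training, cache):
        x = xs[0]
        (pt, pb), (pl, pr) = _pad_amounts(x.shape[1:], self.k, self.s, self.padding)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr)))
        win = _windows(xp, self.k, self.s)
        out = win.mean(axis=(1, 2))
        cache.update(xp_shape=xp.shape, pads=(pt, pb, pl, pr), x_shape=x.shape,
                     oshape=out.shape[1:])
        return np.ascontiguousarray(out, np.float32)

    def backward(self, grad, cache):
        kh, kw = self.k
        sh, sw = self.s
        oh, ow = cache["oshape"]
        dxp = np.zeros(cache["xp_shape"], np.float32)
        g = grad / (kh * kw)
        for i in range(kh):
            for j in range(kw):
                dxp[:, i:i + sh * (oh - 1) + 1:sh, j:j + sw * (ow - 1) + 1:sw] += g
        pt, pb, pl, pr = cache["pads"]
        _, h, w = cache["x_shape"]
        return [dxp[:, pt:pt + h, pl:pl + w]]


class GlobalAvgPool(Layer):
    """Global average pooling, keeping a 1x1 spatial footprint."""

    def forward(self, xs, training, cache):
        x = xs[0]
        cache["shape"] = x.shape
        return x.mean(axis=(1, 2), keepdims=True).astype(np.float32)

    def backward(self, grad, cache):
        _, h, w = cache["shape"]
        return [np.broadcast_to(grad / (h * w), cache["shape"]).astype(np.float32)]


class UpSampling2D(Layer):
    """Nearest-neighbour upsampling by an integer factor."""

    def __init__(self, factor: int = 2, name=None):
        super().__init__(name)
        self.f = int(factor)

    def forward(self, xs, training, cache):
        x = xs[0]
        cache["shape"] = x.shape
        return np.repeat(np.repeat(x, self.f, axis=1), self.f, axis=2)

    def backward(self, grad, cache):
        c, h, w = cache["shape"]
        f = self.f
        return [grad.reshape(c, h, f, w, f).sum(axis=(2, 4))]


class Concatenate(Layer):
    """Channel-axis concatenation."""

    def out_channels(self, in_channels):
        return sum(in_channels)

    def forward(self, xs, training, cache):
        cache["splits"] = [x.shape[0] for x in xs]
        return np.concatenate(xs, axis=0)

    def backward(self, grad, cache):
        out, at = [], 0
        for c in cache["splits"]:
            out.append(grad[at:at + c])
            at += c
        return out


class Add(Layer):
    def forward(self, xs, training, cache):
        cache["n"] = len(xs)
        out = xs[0].copy()
        for x in xs[1:]:
            out += x
        return out

    def backward(self, grad, cache):
        return [grad] * cache["n"]


class Multiply(Layer):
    """Elementwise product with broadcasting (used for squeeze-excite gates)."""

    def out_channels(self, in_channels):
        return max(in_channels)

    def forward(self, xs, training, cache):
        a, b = xs
        cache["a"], cache["b"] = a, b
        return (a * b).astype(np.float32)

    def backward(self, grad, cache):
        a, b = cache["a"], cache["b"]
        ga, gb = grad * b, grad * a
        if ga.shape != a.shape:  # un-broadcast
            ga = ga.sum(axis=(1, 2), keepdims=True)
        if gb.shape != b.shape:
            gb = gb.sum(axis=(1, 2), keepdims=True)
        return [ga.astype(np.float32), gb.astype(np.float32)]


class ZeroPadding2D(Layer):
    def __init__(self, padding=1, name=None):
        super().__init__(name)
        self.p = _pair(padding)

    def forward(self, xs, training, cache):
        ph, pw = self.p
        return np.pad(xs[0], ((0, 0), (ph, ph), (pw, pw)))

    def backward(self, grad, cache):
        ph, pw = self.p
        h = grad.shape[1] - 2 * ph
        w = grad.shape[2] - 2 * pw
        return [grad[:, ph:ph + h, pw:pw + w]]
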