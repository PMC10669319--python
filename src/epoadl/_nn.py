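"""Minimal NumPy CNN runtime: layers with explicit forward/backward passes.

Only what the shuffle-style backbone needs is implemented — grouped and
depthwise convolutions (im2col + BLAS matmul), batch norm, ReLU, pooling,
a linear head and Adam. Tensors are NCHW float32; every layer caches what
its backward pass needs, so one forward must precede each backward.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Module",
    "Conv2d",
    "DepthwiseConv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "AvgPool2d",
    "GlobalAvgPool",
    "Linear",
    "ChannelShuffle",
    "softmax",
    "softmax_cross_entropy",
    "Adam",
]


class Module:
    """Base: subclasses store parameters/grads in ``self.params``/``self.grads``."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.training = True

    def parameters(self):
        yield from ((self, k) for k in self.params)

    def children(self):
        return []

    def modules(self):
        yield self
        for ch in self.children():
            yield from ch.modules()

    def set_training(self, flag: bool) -> None:
        for m in self.modules():
            m.training = flag

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


def _windows(xp: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(N, C, Ho, Wo, k, k) sliding windows over a padded NCHW tensor."""
    v = sliding_window_view(xp, (k, k), axis=(2, 3))
    return v[:, :, ::stride, ::stride]


def _pad(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


class Conv2d(Module):
    """Grouped 2-D convolution, no bias (always followed by batch norm here).

    1x1 convolutions (the bulk of the network) take a batched-matmul fast
    path; k > 1 goes through im2col.
    """

    def __init__(self, in_ch, out_ch, k, stride=1, pad=0, groups=1, rng=None):
        super().__init__()
        if in_ch % groups or out_ch % groups:
            raise ValueError(
                f"channels ({in_ch}->{out_ch}) must be divisible by groups={groups}"
            )
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, k
        self.stride, self.pad, self.groups = stride, pad, groups
        rng = rng or np.random.default_rng()
        fan_in = (in_ch // groups) * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch // groups, k, k))
        self.params["w"] = w.astype(np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.k == 1 and self.stride == 1 and self.pad == 0:
            return self._forward_1x1(x)
        return self._forward_im2col(x)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        if self.k == 1 and self.stride == 1 and self.pad == 0:
            return self._backward_1x1(gout)
        return self._backward_im2col(gout)

    # --- 1x1 fast path ----------------------------------------------------
    def _forward_1x1(self, x: np.ndarray) -> np.ndarray:
        N, C, H, W = x.shape
        g = self.groups
        cg, og = C // g, self.out_ch // g
        xg = np.ascontiguousarray(x).reshape(N, g, cg, H * W)
        self._xg, self._hw = xg, (H, W)
        w = self.params["w"].reshape(g, og, cg)
        out = np.matmul(w[None], xg)  # (N, g, og, HW)
        return out.reshape(N, self.out_ch, H, W)

    def _backward_1x1(self, gout: np.ndarray) -> np.ndarray:
        N = gout.shape[0]
        H, W = self._hw
        g = self.groups
        cg, og = self.in_ch // g, self.out_ch // g
        go = np.ascontiguousarray(gout).reshape(N, g, og, H * W)
        w = self.params["w"].reshape(g, og, cg)
        gw = np.einsum("ngol,ngcl->goc", go, self._xg, optimize=True)
        self.grads["w"] = gw.reshape(self.params["w"].shape).astype(np.float32)
        gx = np.matmul(w.transpose(0, 2, 1)[None], go)  # (N, g, cg, HW)
        self._xg = None
        return gx.reshape(N, self.in_ch, H, W)

    # --- general path -------------------------------------------------------
    def _forward_im2col(self, x: np.ndarray) -> np.ndarray:
        N, C, H, W = x.shape
        k, s, p, g = self.k, self.stride, self.pad, self.groups
        xp = _pad(x, p)
        self._in_shape, self._pad_shape = x.shape, xp.shape
        Ho = (H + 2 * p - k) // s + 1
        Wo = (W + 2 * p - k) // s + 1
        cg, og = C // g, self.out_ch // g
        w = self.params["w"].reshape(g, og, cg * k * k)
        out = np.empty((N, self.out_ch, Ho, Wo), dtype=np.float32)
        self._cols = []
        for gi in range(g):
            win = _windows(xp[:, gi * cg : (gi + 1) * cg], k, s)  # (N,cg,Ho,Wo,k,k)
            cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(N * Ho * Wo, cg * k * k)
            self._cols.append(np.ascontiguousarray(cols))
            out[:, gi * og : (gi + 1) * og] = (
                (cols @ w[gi].T).reshape(N, Ho, Wo, og).transpose(0, 3, 1, 2)
            )
        self._out_hw = (Ho, Wo)
        return out

    def _backward_im2col(self, gout: np.ndarray) -> np.ndarray:
        N, C, H, W = self._in_shape
        k, s, p, g = self.k, self.stride, self.pad, self.groups
        Ho, Wo = self._out_hw
        cg, og = C // g, self.out_ch // g
        w = self.params["w"].reshape(g, og, cg * k * k)
        gw = np.empty_like(w)
        gxp = np.zeros(self._pad_shape, dtype=np.float32)
        for gi in range(g):
            go = gout[:, gi * og : (gi + 1) * og].transpose(0, 2, 3, 1).reshape(-1, og)
            gw[gi] = go.T @ self._cols[gi]
            gcols = (go @ w[gi]).reshape(N, Ho, Wo, cg, k, k).transpose(0, 3, 1, 2, 4, 5)
            sl = gxp[:, gi * cg : (gi + 1) * cg]
            for i in range(k):
                for j in range(k):
                    sl[:, :, i : i + s * Ho : s, j : j + s * Wo : s] += gcols[:, :, :, :, i, j]
        self.grads["w"] = gw.reshape(self.params["w"].shape)
        self._cols = None
        return gxp[:, :, p : p + H, p : p + W] if p else gxp


class DepthwiseConv2d(Module):
    """Per-channel k x k convolution (one filter per channel)."""

    def __init__(self, channels, k, stride=1, pad=0, rng=None):
        super().__init__()
        self.ch, self.k, self.stride, self.pad = channels, k, stride, pad
        rng = rng or np.random.default_rng()
        w = rng.normal(0.0, np.sqrt(2.0 / (k * k)), size=(channels, k, k))
        self.params["w"] = w.astype(np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s = self.k, self.stride
        xp = _pad(x, self.pad)
        self._in_shape, self._xp = x.shape, xp
        Ho = (xp.shape[2] - k) // s + 1
        Wo = (xp.shape[3] - k) // s + 1
        w = self.params["w"]
        out = np.zeros((x.shape[0], self.ch, Ho, Wo), dtype=np.float32)
        for i in range(k):  # shift-accumulate: cheaper than building windows
            for j in range(k):
                out += xp[:, :, i : i + s * Ho : s, j : j + s * Wo : s] * w[None, :, i, j, None, None]
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        k, s, p = self.k, self.stride, self.pad
        N, C, H, W = self._in_shape
        Ho, Wo = gout.shape[2], gout.shape[3]
        w = self.params["w"]
        gw = np.empty_like(w)
        gxp = np.zeros(self._xp.shape, dtype=np.float32)
        for i in range(k):
            for j in range(k):
                xs = self._xp[:, :, i : i + s * Ho : s, j : j + s * Wo : s]
                gw[:, i, j] = np.sum(gout * xs, axis=(0, 2, 3))
                gxp[:, :, i : i + s * Ho : s, j : j + s * Wo : s] += (
                    gout * w[None, :, i, j, None, None]
                )
        self.grads["w"] = gw
        self._xp = None
        return gxp[:, :, p : p + H, p : p + W] if p else gxp


class BatchNorm2d(Module):
    def __init__(self, channels, momentum=0.1, eps=1e-5):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params["gamma"] = np.ones(channels, dtype=np.float32)
        self.params["beta"] = np.zeros(channels, dtype=np.float32)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2, 3), dtype=np.float32)
            var = np.mean(np.square(x), axis=(0, 2, 3), dtype=np.float32) - mean * mean
            np.maximum(var, 0.0, out=var)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._xhat, self._inv = xhat, inv
        return self.params["gamma"][None, :, None, None] * xhat + self.params["beta"][
            None, :, None, None
        ]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        self.grads["gamma"] = np.sum(gout * xhat, axis=(0, 2, 3))
        self.grads["beta"] = np.sum(gout, axis=(0, 2, 3))
        if not self.training:
            return gout * (self.params["gamma"] * inv)[None, :, None, None]
        m = gout.shape[0] * gout.shape[2] * gout.shape[3]
        gmean = gout.mean(axis=(0, 2, 3))
        gdot = (gout * xhat).mean(axis=(0, 2, 3))
        gx = (self.params["gamma"] * inv)[None, :, None, None] * (
            gout - gmean[None, :, None, None] - xhat * gdot[None, :, None, None]
        )
        self._xhat = None
        return gx.astype(np.float32)


class ReLU(Module):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, gout):
        g = gout * self._mask
        self._mask = None
        return g


class MaxPool2d(Module):
    def __init__(self, k=3, stride=2, pad=1):
        super().__init__()
        self.k, self.stride, self.pad = k, stride, pad

    def forward(self, x):
        xp = _pad(x, self.pad) if self.pad else x
        if self.pad:  # pad with -inf so padding never wins the max
            xp = xp.copy()
            xp[:, :, : self.pad] = -np.inf
            xp[:, :, -self.pad :] = -np.inf
            xp[:, :, :, : self.pad] = -np.inf
            xp[:, :, :, -self.pad :] = -np.inf
        win = _windows(xp, self.k, self.stride)
        N, C, Ho, Wo = win.shape[:4]
        flat = win.reshape(N, C, Ho, Wo, -1)
        self._arg = flat.argmax(axis=-1)
        self._in_shape, self._pad_shape = x.shape, xp.shape
        return flat.max(axis=-1).astype(np.float32)

    def backward(self, gout):
        k, s, p = self.k, self.stride, self.pad
        N, C, Ho, Wo = gout.shape
        gi, gj = np.unravel_index(self._arg, (k, k))
        n, c, ho, wo = np.indices((N, C, Ho, Wo), sparse=False)
        h = ho * s + gi
        w = wo * s + gj
        gxp = np.zeros(self._pad_shape, dtype=np.float32)
        np.add.at(gxp, (n, c, h, w), gout)
        _, _, H, W = self._in_shape
        self._arg = None
        return gxp[:, :, p : p + H, p : p + W] if p else gxp


class AvgPool2d(Module):
    def __init__(self, k=3, stride=2, pad=1):
        super().__init__()
        self.k, self.stride, self.pad = k, stride, pad

    def forward(self, x):
        xp = _pad(x, self.pad)
        self._in_shape, self._pad_shape = x.shape, xp.shape
        win = _windows(xp, self.k, self.stride)
        return win.mean(axis=(-2, -1)).astype(np.float32)

    def backward(self, gout):
        k, s, p = self.k, self.stride, self.pad
        N, C, Ho, Wo = gout.shape
        g = gout / (k * k)
        gxp = np.zeros(self._pad_shape, dtype=np.float32)
        for i in range(k):
            for j in range(k):
                gxp[:, :, i : i + s * Ho : s, j : j + s * Wo : s] += g
        _, _, H, W = self._in_shape
        return gxp[:, :, p : p + H, p : p + W] if p else gxp


class GlobalAvgPool(Module):
    def forward(self, x):
        self._in_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, gout):
        N, C, H, W = self._in_shape
        return np.broadcast_to(gout[:, :, None, None] / (H * W), self._in_shape).astype(
            np.float32
        )


class Linear(Module):
    def __init__(self, n_in, n_out, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.params["w"] = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_out, n_in)).astype(
            np.float32
        )
        self.params["b"] = np.zeros(n_out, dtype=np.float32)

    def forward(self, x):
        self._x = x
        return x @ self.params["w"].T + self.params["b"]

    def backward(self, gout):
        self.grads["w"] = gout.T @ self._x
        self.grads["b"] = gout.sum(axis=0)
        g = gout @ self.params["w"]
        self._x = None
        return g


class ChannelShuffle(Module):
    """Fixed channel permutation: reshape (g, C/g) -> transpose -> flatten."""

    def __init__(self, groups):
        super().__init__()
        self.groups = groups

    def forward(self, x):
        N, C, H, W = x.shape
        g = self.groups
        if C % g:
            raise ValueError(f"channels {C} not divisible by groups {g}")
        return x.reshape(N, g, C // g, H, W).transpose(0, 2, 1, 3, 4).reshape(N, C, H, W)

    def backward(self, gout):
        N, C, H, W = gout.shape
        g = self.groups  # inverse permutation: shuffle with C//g groups
        return (
            gout.reshape(N, C // g, g, H, W).transpose(0, 2, 1, 3, 4).reshape(N, C, H, W)
        )


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray):
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.mean(np.log(np.maximum(p[np.arange(n), y], 1e-12))))
    g = p.copy()
    g[np.arange(n), y] -= 1.0
    return loss, (g / n).astype(np.float32)


class Adam:
    def __init__(self, modules, lr=1e-3, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        self.slots = [(m, k) for mod in modules for m, k in mod.parameters()]
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(m.params[k]) for m, k in self.slots]
        self.v = [np.zeros_like(m.params[k]) for m, k in self.slots]
        self.t = 0

    def step(self):
        self.t += 1
        for i, (mod, key) in enumerate(self.slots):
            g = mod.grads.get(key)
            if g is None:
                continue
            if self.weight_decay:
                g = g + self.weight_decay * mod.params[key]
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            mod.params[key] -= (self.lr * mh / (np.sqrt(vh) + self.eps)).astype(np.float32)
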