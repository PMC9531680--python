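"""Spatial and loss primitives for the autodiff engine.

Convolutions are computed by the shift-and-accumulate method (one einsum per
kernel offset), which is exact and fast enough at the tile sizes this package
operates on.  Layout convention is NCHW throughout.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = [
    "conv2d",
    "avg_pool2d",
    "upsample_nearest2d",
    "softmax",
    "log_softmax",
    "cross_entropy",
    "bce_with_logits",
]


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation. x: (N,C,H,W), w: (O,C,kh,kw), b: (O,)."""
    xd, wd = x.data, w.data
    n, c, h, wid = xd.shape
    o, c2, kh, kw = wd.shape
    if c != c2:
        raise ValueError(f"channel mismatch: input has {c}, kernel expects {c2}")
    s, p = int(stride), int(padding)
    xp = np.pad(xd, ((0, 0), (0, 0), (p, p), (p, p))) if p else xd
    oh = (h + 2 * p - kh) // s + 1
    ow = (wid + 2 * p - kw) // s + 1
    out = np.zeros((n, o, oh, ow))
    for u in range(kh):
        for v in range(kw):
            xs = xp[:, :, u:u + oh * s:s, v:v + ow * s:s]
            out += np.einsum("nchw,oc->nohw", xs, wd[:, :, u, v], optimize=True)
    if b is not None:
        out += b.data.reshape(1, o, 1, 1)
    parents = [x, w] + ([b] if b is not None else [])
    res = Tensor._make(out, parents, None)

    def backward(g):
        gxp = np.zeros_like(xp)
        gw = np.zeros_like(wd)
        for u in range(kh):
            for v in range(kw):
                xs = xp[:, :, u:u + oh * s:s, v:v + ow * s:s]
                gw[:, :, u, v] = np.einsum("nohw,nchw->oc", g, xs, optimize=True)
                gxp[:, :, u:u + oh * s:s, v:v + ow * s:s] += np.einsum(
                    "nohw,oc->nchw", g, wd[:, :, u, v], optimize=True)
        gx = gxp[:, :, p:p + h, p:p + wid] if p else gxp
        if b is not None:
            return (gx, gw, g.sum(axis=(0, 2, 3)))
        return (gx, gw)

    res._backward = backward
    return res


def avg_pool2d(x: Tensor, k: int) -> Tensor:
    n, c, h, w = x.shape
    if h % k or w % k:
        raise ValueError(f"spatial dims {h}x{w} not divisible by pool size {k}")
    oh, ow = h // k, w // k
    val = x.data.reshape(n, c, oh, k, ow, k).mean(axis=(3, 5))
    out = Tensor._make(val, (x,), None)

    def backward(g):
        gx = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
        return (gx,)

    out._backward = backward
    return out


def upsample_nearest2d(x: Tensor, k: int) -> Tensor:
    n, c, h, w = x.shape
    val = np.repeat(np.repeat(x.data, k, axis=2), k, axis=3)
    out = Tensor._make(val, (x,), None)

    def backward(g):
        return (g.reshape(n, c, h, k, w, k).sum(axis=(3, 5)),)

    out._backward = backward
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = x.data.max(axis=axis, keepdims=True)  # constant; no grad through it
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = x.data.max(axis=axis, keepdims=True)
    xs = x - shift
    return xs - xs.exp().sum(axis=axis, keepdims=True).log()


def cross_entropy(logits: Tensor, target: np.ndarray,
                  ignore_mask: np.ndarray | None = None,
                  axis: int = -1) -> Tensor:
    """Mean negative log-likelihood of integer ``target`` labels.

    ``ignore_mask`` marks positions (same shape as ``target``) excluded from
    both the numerator and the denominator; an all-ignored batch contributes
    exactly zero loss.
    """
    target = np.asarray(target)
    nclass = logits.shape[axis]
    onehot = np.eye(nclass)[target]
    if axis != -1 and axis != logits.ndim - 1:
        onehot = np.moveaxis(onehot, -1, axis)
    lp = log_softmax(logits, axis=axis)
    picked = (lp * onehot).sum(axis=axis)
    if ignore_mask is not None:
        keep = (~np.asarray(ignore_mask, dtype=bool)).astype(np.float64)
        denom = keep.sum()
        if denom == 0:
            return (picked * 0.0).sum()
        return -(picked * keep).sum() / denom
    return -picked.mean()


def bce_with_logits(logits: Tensor, target: np.ndarray,
                    weight: np.ndarray | None = None) -> Tensor:
    """Stable elementwise binary cross-entropy, averaged (weighted mean)."""
    target = np.asarray(target, dtype=np.float64)
    # max(x,0) - x*y + log(1+exp(-|x|))
    loss = logits.relu() - logits * target + (-abs(logits)).softplus()
    if weight is not None:
        w = np.asarray(weight, dtype=np.float64)
        return (loss * w).sum() / w.sum()
    return loss.mean()


def _abs(t: Tensor) -> Tensor:
    mask = np.sign(t.data)
    out = Tensor._make(np.abs(t.data), (t,), None)
    out._backward = lambda g: (g * mask,)
    return out


# used by bce_with_logits via abs(); register as builtin-style helper
Tensor.__abs__ = _abs
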