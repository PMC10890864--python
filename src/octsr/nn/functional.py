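"""Differentiable array operations used by the networks (NCHW layout)."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat  # noqa: F401  (concat re-exported)


def _im2col(x: np.ndarray, kh: int, kw: int, sh: int, sw: int, ph: int, pw: int):
    """Return (cols, (N, C, Ho, Wo, Hp, Wp)); cols is (N*Ho*Wo, C*kh*kw)."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else x
    hp, wp = xp.shape[2], xp.shape[3]
    ho = (hp - kh) // sh + 1
    wo = (wp - kw) // sw + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::sh, ::sw]  # N, C, Ho, Wo, kh, kw
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
    return np.ascontiguousarray(cols), (n, c, ho, wo, hp, wp)


def _col2im(cols_grad: np.ndarray, meta, kh, kw, sh, sw, ph, pw, h, w):
    n, c, ho, wo, hp, wp = meta
    g = cols_grad.reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
    dxp = np.zeros((n, c, hp, wp), dtype=cols_grad.dtype)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + sh * ho : sh, j : j + sw * wo : sw] += g[:, :, :, :, i, j]
    if ph or pw:
        return dxp[:, :, ph : ph + h, pw : pw + w]
    return dxp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, stride: int = 1,
           padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation) of NCHW input with OIHW weights."""
    co, ci, kh, kw = weight.shape
    n, c, h, w = x.shape
    if c != ci:
        raise ValueError(f"conv2d: input has {c} channels, weight expects {ci}")
    cols, meta = _im2col(x.data, kh, kw, stride, stride, padding, padding)
    wmat = weight.data.reshape(co, ci * kh * kw)
    out = cols @ wmat.T
    if bias is not None:
        out = out + bias.data
    _, _, ho, wo, _, _ = meta
    out = out.reshape(n, ho, wo, co).transpose(0, 3, 1, 2)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def bwd(g):
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, co)
        if weight.requires_grad:
            weight._accum((gmat.T @ cols).reshape(co, ci, kh, kw))
        if bias is not None and bias.requires_grad:
            bias._accum(gmat.sum(axis=0))
        if x.requires_grad:
            cols_grad = gmat @ wmat
            x._accum(_col2im(cols_grad, meta, kh, kw, stride, stride,
                             padding, padding, h, w))

    return Tensor._make(np.ascontiguousarray(out), parents, bwd)


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel normalisation over the spatial axes, affine."""
    n, c, h, w = x.shape
    xd = x.data
    mu = xd.mean(axis=(2, 3), keepdims=True)
    xc = xd - mu
    var = (xc * xc).mean(axis=(2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    gam = gamma.data.reshape(1, c, 1, 1)
    out = gam * xhat + beta.data.reshape(1, c, 1, 1)

    def bwd(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            m = h * w
            gh = g * gam  # dL/dxhat
            t1 = gh
            t2 = gh.mean(axis=(2, 3), keepdims=True)
            t3 = xhat * (gh * xhat).mean(axis=(2, 3), keepdims=True)
            x._accum(inv * (t1 - t2 - t3))

    return Tensor._make(out, (x, gamma, beta), bwd)


def pixel_shuffle(x: Tensor, s: int) -> Tensor:
    """Rearrange (N, C*s^2, H, W) -> (N, C, H*s, W*s) (sub-pixel convolution).

    output[n, c, y, x] = input[n, c*s^2 + (y mod s)*s + (x mod s), y//s, x//s]
    """
    n, c2, h, w = x.shape
    if c2 % (s * s):
        raise ValueError("pixel_shuffle: channels not divisible by s^2")
    c = c2 // (s * s)
    return (
        x.reshape(n, c, s, s, h, w)
        .transpose(0, 1, 4, 2, 5, 3)
        .reshape(n, c, h * s, w * s)
    )


def avg_pool(x: Tensor, k: int) -> Tensor:
    """Non-overlapping k x k average pooling (spatial dims divisible by k)."""
    n, c, h, w = x.shape
    if h % k or w % k:
        raise ValueError("avg_pool: spatial size not divisible by kernel")
    return x.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))


def warp_bilinear(feat: Tensor, flow: np.ndarray) -> Tensor:
    """Backward-warp ``feat`` by ``flow`` with bilinear sampling.

    ``flow`` is a fixed (non-differentiated) array of shape (N, 2, H, W)
    holding (dx, dy) displacements in pixels: output(p) = feat(p + flow(p)).
    Samples outside the grid clamp to the border.  Differentiable in ``feat``.
    """
    n, c, h, w = feat.shape
    flow = np.asarray(flow)
    if flow.shape != (n, 2, h, w):
        raise ValueError(f"warp: flow shape {flow.shape} != {(n, 2, h, w)}")
    if not np.all(np.isfinite(flow)):
        raise ValueError("warp: non-finite flow")
    gy, gx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    sx = gx[None] + flow[:, 0]
    sy = gy[None] + flow[:, 1]
    sx = np.clip(sx, 0.0, w - 1.0)
    sy = np.clip(sy, 0.0, h - 1.0)
    x0 = np.floor(sx).astype(np.int64)
    y0 = np.floor(sy).astype(np.int64)
    x1 = np.minimum(x0 + 1, w - 1)
    y1 = np.minimum(y0 + 1, h - 1)
    fx = (sx - x0).astype(feat.dtype)
    fy = (sy - y0).astype(feat.dtype)
    w00 = (1 - fx) * (1 - fy)
    w01 = fx * (1 - fy)
    w10 = (1 - fx) * fy
    w11 = fx * fy

    fd = feat.data
    bidx = np.arange(n)[:, None, None]
    out = (
        w00[:, None] * fd[bidx[:, None], np.arange(c)[None, :, None, None], y0[:, None], x0[:, None]]
        + w01[:, None] * fd[bidx[:, None], np.arange(c)[None, :, None, None], y0[:, None], x1[:, None]]
        + w10[:, None] * fd[bidx[:, None], np.arange(c)[None, :, None, None], y1[:, None], x0[:, None]]
        + w11[:, None] * fd[bidx[:, None], np.arange(c)[None, :, None, None], y1[:, None], x1[:, None]]
    )

    def bwd(g):
        if not feat.requires_grad:
            return
        buf = np.zeros_like(fd).reshape(n, c, h * w)
        gg = g.reshape(n, c, h * w)
        for corner_y, corner_x, wgt in ((y0, x0, w00), (y0, x1, w01),
                                        (y1, x0, w10), (y1, x1, w11)):
            flat = (corner_y * w + corner_x).reshape(n, 1, h * w)
            vals = gg * wgt.reshape(n, 1, h * w)
            for b in range(n):
                np.add.at(buf[b], (slice(None), flat[b, 0]), vals[b])
        feat._accum(buf.reshape(n, c, h, w))

    return Tensor._make(out.astype(fd.dtype, copy=False), (feat,), bwd)


def gather_spatial(x: Tensor, ys: np.ndarray, xs: np.ndarray) -> Tensor:
    """Pick feature vectors at spatial sites: (N, C, H, W) -> (N, P, C)."""
    n, c, h, w = x.shape
    flat = np.asarray(ys) * w + np.asarray(xs)  # (P,)
    out = x.data.reshape(n, c, h * w)[:, :, flat].transpose(0, 2, 1)

    def bwd(g):
        if not x.requires_grad:
            return
        buf = np.zeros((n, c, h * w), dtype=x.dtype)
        np.add.at(buf, (slice(None), slice(None), flat), g.transpose(0, 2, 1))
        x._accum(buf.reshape(n, c, h, w))

    return Tensor._make(np.ascontiguousarray(out), (x,), bwd)


def l2_normalize(x: Tensor, axis: int = -1, eps: float = 1e-10) -> Tensor:
    norm = ((x * x).sum(axis=axis, keepdims=True) + eps).sqrt()
    return x / norm


def mse(a: Tensor, b: Tensor) -> Tensor:
    d = a - b
    return (d * d).mean()
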