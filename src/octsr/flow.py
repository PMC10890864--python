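"""Dense optical-flow estimation between adjacent frames.

The default backend is a self-contained coarse-to-fine block-matching
estimator: a 3-level image pyramid, an exhaustive local search over integer
displacements scored by locally averaged squared difference, parabolic
sub-pixel refinement of the winning displacement, and Gaussian smoothing of
the field at every level.  It is not trained and is treated as a fixed
module — gradients never flow through it, mirroring the use of a frozen
flow network inside recurrent super-resolution models.

Convention: ``estimate_flow(ref, mov)`` returns ``flow`` of shape (2, H, W)
with channels (dx, dy) such that sampling ``mov`` at ``p + flow(p)``
reconstructs ``ref(p)`` (backward warping).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

BACKENDS = ("builtin_pyramidal", "zero")


def estimate_flow(ref: np.ndarray, mov: np.ndarray, backend: str = "builtin_pyramidal",
                  levels: int = 3, radius: int = 3, window: int = 7,
                  smooth_sigma: float = 2.0) -> np.ndarray:
    ref = np.asarray(ref, dtype=np.float64)
    mov = np.asarray(mov, dtype=np.float64)
    if ref.shape != mov.shape or ref.ndim != 2:
        raise ValueError(f"frame shapes differ or not 2-D: {ref.shape} vs {mov.shape}")
    if backend == "zero":
        return np.zeros((2,) + ref.shape, dtype=np.float32)
    if backend != "builtin_pyramidal":
        raise ValueError(f"unknown flow backend {backend!r}; choose from {BACKENDS}")

    pyr_ref = _pyramid(ref, levels)
    pyr_mov = _pyramid(mov, levels)
    flow = np.zeros((2,) + pyr_ref[-1].shape)
    for lvl in range(levels - 1, -1, -1):
        r, m = pyr_ref[lvl], pyr_mov[lvl]
        if flow.shape[1:] != r.shape:
            flow = 2.0 * np.stack([_resize_bilinear(flow[0], r.shape),
                                   _resize_bilinear(flow[1], r.shape)])
        warped = _warp_backward(m, flow)
        flow = flow + _match_residual(r, warped, radius, window)
        flow[0] = ndimage.gaussian_filter(flow[0], smooth_sigma)
        flow[1] = ndimage.gaussian_filter(flow[1], smooth_sigma)
    return flow.astype(np.float32)


def sequence_flows(seq: np.ndarray, backend: str = "builtin_pyramidal", **kw):
    """Flows for both propagation directions of a (T, H, W) clip.

    Returns ``(backward, forward)``: ``backward[t] = flow(x_t, x_{t+1})`` for
    t = 0..T-2 and ``forward[t] = flow(x_{t+1}, x_t)`` aligning the previous
    frame to t+1.
    """
    t_frames = seq.shape[0]
    bwd = [estimate_flow(seq[t], seq[t + 1], backend, **kw) for t in range(t_frames - 1)]
    fwd = [estimate_flow(seq[t + 1], seq[t], backend, **kw) for t in range(t_frames - 1)]
    return bwd, fwd


def _pyramid(img: np.ndarray, levels: int) -> list[np.ndarray]:
    pyr = [img]
    for _ in range(levels - 1):
        cur = ndimage.gaussian_filter(pyr[-1], 1.0)
        pyr.append(cur[::2, ::2])
    return pyr


def _resize_bilinear(img: np.ndarray, shape) -> np.ndarray:
    h, w = img.shape
    hh, ww = shape
    ys = np.linspace(0, h - 1, hh)
    xs = np.linspace(0, w - 1, ww)
    grid = np.meshgrid(ys, xs, indexing="ij")
    return ndimage.map_coordinates(img, grid, order=1, mode="nearest")


def _warp_backward(img: np.ndarray, flow: np.ndarray) -> np.ndarray:
    h, w = img.shape
    gy, gx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    return ndimage.map_coordinates(img, [gy + flow[1], gx + flow[0]],
                                   order=1, mode="nearest")


def _match_residual(ref: np.ndarray, mov: np.ndarray, radius: int, window: int):
    """Integer displacement minimising windowed SSD, parabolically refined."""
    h, w = ref.shape
    r = min(radius, max(1, min(h, w) // 4))
    n_d = 2 * r + 1
    cost = np.empty((n_d, n_d, h, w))
    for iy, dy in enumerate(range(-r, r + 1)):
        for ix, dx in enumerate(range(-r, r + 1)):
            shifted = _shift_edge(mov, dy, dx)
            diff = ref - shifted
            # The tiny displacement penalty breaks ties toward zero motion in
            # textureless regions where every candidate matches equally well.
            cost[iy, ix] = ndimage.uniform_filter(diff * diff, size=window) \
                + 1e-6 * (dy * dy + dx * dx)
    flat = cost.reshape(n_d * n_d, h, w)
    best = flat.argmin(axis=0)
    by, bx = np.divmod(best, n_d)

    fy = (by - r).astype(np.float64)
    fx = (bx - r).astype(np.float64)
    jj, kk = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    # Parabolic refinement along each displacement axis (interior optima only).
    for axis, coord in ((0, by), (1, bx)):
        interior = (coord > 0) & (coord < n_d - 1)
        lo = np.where(interior, coord - 1, coord)
        hi = np.where(interior, coord + 1, coord)
        if axis == 0:
            c_lo, c0, c_hi = cost[lo, bx, jj, kk], cost[by, bx, jj, kk], cost[hi, bx, jj, kk]
        else:
            c_lo, c0, c_hi = cost[by, lo, jj, kk], cost[by, bx, jj, kk], cost[by, hi, jj, kk]
        denom = c_lo - 2 * c0 + c_hi
        # Refine only at strict interior minima; flat cost valleys (e.g.
        # textureless regions or an exact match) keep the integer estimate.
        valid = (interior & (denom > 1e-9) & (c0 < np.minimum(c_lo, c_hi))
                 & (c0 > 1e-10))  # a perfect match needs no sub-pixel shift
        delta = np.where(valid, 0.5 * (c_lo - c_hi) / np.maximum(denom, 1e-12), 0.0)
        delta = np.clip(delta, -0.5, 0.5)
        if axis == 0:
            fy += delta
        else:
            fx += delta
    return np.stack([fx, fy])


def _shift_edge(img: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Shift so that output(p) = img(p + (dy, dx)), edges replicated."""
    h, w = img.shape
    ys = np.clip(np.arange(h) + dy, 0, h - 1)
    xs = np.clip(np.arange(w) + dx, 0, w - 1)
    return img[np.ix_(ys, xs)]
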