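"""Separable image resampling expressed as linear operators.

Both bicubic interpolation and pixel-area (``inter-area``) resampling are
separable: a resize from (H, W) to (H', W') is ``R_h @ X @ R_w.T`` with 1-D
weight matrices.  Expressing them as matrices gives exact adjoints for free,
so the network's interpolation layers differentiate through plain matmuls.

Conventions (used everywhere in the package):
  * half-pixel centred sampling, no corner alignment;
  * cubic convolution kernel with a = -0.5 (Catmull-Rom);
  * edges clamped (weights of out-of-range taps folded onto the border pixel).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .tensor import Tensor, as_tensor, matmul, swap_last2

_A = -0.5  # cubic kernel free parameter


def _cubic_kernel(t: np.ndarray) -> np.ndarray:
    t = np.abs(t)
    t2, t3 = t * t, t * t * t
    w = np.where(
        t <= 1.0,
        (_A + 2.0) * t3 - (_A + 3.0) * t2 + 1.0,
        np.where(t < 2.0, _A * t3 - 5.0 * _A * t2 + 8.0 * _A * t - 4.0 * _A, 0.0),
    )
    return w


@lru_cache(maxsize=None)
def bicubic_matrix(n_in: int, n_out: int) -> np.ndarray:
    """(n_out, n_in) interpolation weights; rows sum to 1."""
    scale = n_in / n_out
    out = np.zeros((n_out, n_in), dtype=np.float64)
    for i in range(n_out):
        src = (i + 0.5) * scale - 0.5
        base = int(np.floor(src))
        taps = np.arange(base - 1, base + 3)
        w = _cubic_kernel(src - taps)
        w = w / w.sum()
        taps = np.clip(taps, 0, n_in - 1)  # clamp: fold edge weights inward
        for t, wt in zip(taps, w):
            out[i, t] += wt
    return out.astype(np.float32)


@lru_cache(maxsize=None)
def area_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Exact pixel-area-overlap weights (resampling by pixel area relation)."""
    scale = n_in / n_out
    out = np.zeros((n_out, n_in), dtype=np.float64)
    for i in range(n_out):
        lo, hi = i * scale, (i + 1) * scale
        j0, j1 = int(np.floor(lo)), int(np.ceil(hi))
        for j in range(j0, min(j1, n_in)):
            overlap = min(hi, j + 1) - max(lo, j)
            if overlap > 0:
                out[i, j] = overlap / scale
    return out.astype(np.float32)


def resize_bicubic(x: Tensor | np.ndarray, out_h: int, out_w: int | None = None) -> Tensor:
    """Bicubic resize of the trailing two axes (differentiable)."""
    if out_w is None:
        out_w = out_h
    x = as_tensor(x)
    h, w = x.shape[-2], x.shape[-1]
    if (h, w) == (out_h, out_w):
        return x
    if h != out_h:
        x = matmul(Tensor(bicubic_matrix(h, out_h)), x)
    if w != out_w:
        x = swap_last2(matmul(Tensor(bicubic_matrix(w, out_w)), swap_last2(x)))
    return x


def resize_bicubic_np(x: np.ndarray, out_h: int, out_w: int | None = None) -> np.ndarray:
    """NumPy-only bicubic resize of the trailing two axes."""
    if out_w is None:
        out_w = out_h
    h, w = x.shape[-2], x.shape[-1]
    dtype = x.dtype if x.dtype.kind == "f" else np.float32
    y = x.astype(np.float32, copy=False)
    if h != out_h:
        y = np.einsum("oh,...hw->...ow", bicubic_matrix(h, out_h), y)
    if w != out_w:
        y = np.einsum("ow,...hw->...ho", bicubic_matrix(w, out_w), y)
    return y.astype(dtype, copy=False)


def resize_area_np(x: np.ndarray, out_h: int, out_w: int | None = None) -> np.ndarray:
    """Area-relation resize of the two leading spatial axes of an H×W[×C] array."""
    if out_w is None:
        out_w = out_h
    h, w = x.shape[0], x.shape[1]
    y = x.astype(np.float64, copy=False)
    if h != out_h:
        y = np.einsum("oh,hw...->ow...", area_matrix(h, out_h).astype(np.float64), y)
    if w != out_w:
        y = np.einsum("ow,hw...->ho...", area_matrix(w, out_w).astype(np.float64), y)
    return y


def resize_nearest_np(x: np.ndarray, out_h: int, out_w: int | None = None) -> np.ndarray:
    """Nearest-neighbour resize (label masks; preserves the label set)."""
    if out_w is None:
        out_w = out_h
    h, w = x.shape[0], x.shape[1]
    rows = np.clip(np.round((np.arange(out_h) + 0.5) * h / out_h - 0.5).astype(int), 0, h - 1)
    cols = np.clip(np.round((np.arange(out_w) + 0.5) * w / out_w - 0.5).astype(int), 0, w - 1)
    return x[np.ix_(rows, cols)]
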