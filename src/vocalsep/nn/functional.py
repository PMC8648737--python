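"""Neural-network operations (convolution, pooling, resampling, softmax).

Convolutions use the im2col/fancy-index formulation; the backward pass
scatter-adds column gradients back with ``np.add.at``.  Tensors follow the
NCHW (2-D) and NCL (1-D) layout conventions.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, as_tensor

__all__ = [
    "conv2d",
    "conv1d",
    "conv_transpose1d",
    "max_pool2d",
    "upsample_bilinear2d",
    "log_softmax",
    "overlap_add",
    "dropout",
]


def _im2col(arr: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """Sliding 'same' windows of a padded NCHW array as a strided view:
    (N, C, kh*kw, H*W) where H, W are the unpadded spatial dims."""
    n, c, hp, wp = arr.shape
    h, w = hp - kh + 1, wp - kw + 1
    sn, sc, sh, sw = arr.strides
    view = np.lib.stride_tricks.as_strided(
        arr, shape=(n, c, kh, kw, h, w), strides=(sn, sc, sh, sw, sh, sw)
    )
    return view.reshape(n, c, kh * kw, h * w)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Stride-1, 'same'-padded 2-D convolution.

    x: (N, Cin, H, W); weight: (Cout, Cin, kh, kw) with odd kh, kw.
    """
    x, weight = as_tensor(x), as_tensor(weight)
    n, cin, h, w = x.shape
    cout, cin_w, kh, kw = weight.shape
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input {cin}, weight {cin_w}")
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    cols = np.ascontiguousarray(_im2col(xp, kh, kw)).reshape(n, cin * kh * kw, h * w)
    wmat = weight.data.reshape(cout, cin * kh * kw)
    out = np.matmul(wmat, cols).reshape(n, cout, h, w)
    if bias is not None:
        out = out + bias.data.reshape(1, cout, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        gmat = np.ascontiguousarray(g).reshape(n, cout, h * w)
        if weight.requires_grad:
            gw = np.matmul(gmat, cols.transpose(0, 2, 1)).sum(axis=0)
            weight._accumulate(gw.reshape(weight.shape))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            # input gradient = 'same' convolution of g with the spatially
            # flipped, channel-transposed kernels
            w_rot = np.ascontiguousarray(
                weight.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
            ).reshape(cin, cout * kh * kw)
            gp = np.pad(gmat.reshape(n, cout, h, w), ((0, 0), (0, 0), (ph, ph), (pw, pw)))
            gcols = np.ascontiguousarray(_im2col(gp, kh, kw)).reshape(
                n, cout * kh * kw, h * w
            )
            gx = np.matmul(w_rot, gcols).reshape(n, cin, h, w)
            x._accumulate(gx)

    return Tensor._from_op(out, parents, backward)


def conv1d(x: Tensor, weight: Tensor, bias: Tensor | None = None, stride: int = 1,
           padding: int = 0) -> Tensor:
    """1-D convolution.  x: (N, Cin, L); weight: (Cout, Cin, K)."""
    x, weight = as_tensor(x), as_tensor(weight)
    n, cin, length = x.shape
    cout, cin_w, k = weight.shape
    if cin != cin_w:
        raise ValueError("channel mismatch")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding)))
    lout = (length + 2 * padding - k) // stride + 1
    idx = np.arange(k)[:, None] + stride * np.arange(lout)[None, :]  # (K, Lout)
    cols = xp[:, :, idx]  # (N, Cin, K, Lout)
    wmat = weight.data.reshape(cout, cin * k)
    out = np.einsum("ok,nkl->nol", wmat, cols.reshape(n, cin * k, lout))
    if bias is not None:
        out = out + bias.data.reshape(1, cout, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        if weight.requires_grad:
            gw = np.einsum("nol,nkl->ok", g, cols.reshape(n, cin * k, lout))
            weight._accumulate(gw.reshape(weight.shape))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2)))
        if x.requires_grad:
            gcols = np.einsum("ok,nol->nkl", wmat, g).reshape(n, cin, k, lout)
            gxp = np.zeros_like(xp)
            np.add.at(gxp, (slice(None), slice(None), idx), gcols)
            x._accumulate(gxp[:, :, padding : padding + length])

    return Tensor._from_op(out, parents, backward)


def conv_transpose1d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
                     stride: int = 1, padding: int = 0) -> Tensor:
    """Transposed 1-D convolution (the adjoint of :func:`conv1d`).

    x: (N, Cin, L); weight: (Cin, Cout, K).  Output length
    ``(L - 1) * stride + K - 2 * padding``.
    """
    x, weight = as_tensor(x), as_tensor(weight)
    n, cin, lin = x.shape
    cin_w, cout, k = weight.shape
    if cin != cin_w:
        raise ValueError("channel mismatch")
    lfull = (lin - 1) * stride + k
    idx = np.arange(k)[:, None] + stride * np.arange(lin)[None, :]  # (K, Lin)
    # scatter contributions: out[idx[t, l]] += sum_ci w[ci, :, t] * x[ci, l]
    contrib = np.einsum("iok,nil->nokl", weight.data, x.data)  # (N, Cout, K, Lin)
    out_full = np.zeros((n, cout, lfull), dtype=contrib.dtype)
    np.add.at(out_full, (slice(None), slice(None), idx), contrib)
    out = out_full[:, :, padding : lfull - padding if padding else lfull]
    if bias is not None:
        out = out + bias.data.reshape(1, cout, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        gfull = np.zeros((n, cout, lfull), dtype=g.dtype)
        gfull[:, :, padding : lfull - padding if padding else lfull] = g
        gcontrib = gfull[:, :, idx]  # (N, Cout, K, Lin)
        if x.requires_grad:
            x._accumulate(np.einsum("iok,nokl->nil", weight.data, gcontrib))
        if weight.requires_grad:
            weight._accumulate(np.einsum("nil,nokl->iok", x.data, gcontrib))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2)))

    return Tensor._from_op(out, parents, backward)


def max_pool2d(x: Tensor, pool: int) -> Tensor:
    """Non-overlapping max pooling with square pool size; H, W must divide."""
    x = as_tensor(x)
    n, c, h, w = x.shape
    if h % pool or w % pool:
        raise ValueError(
            f"max_pool2d: spatial dims ({h},{w}) not divisible by pool {pool}; "
            "pad the representation first"
        )
    hw, ww = h // pool, w // pool
    xr = (
        x.data.reshape(n, c, hw, pool, ww, pool)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, c, hw, ww, pool * pool)
    )
    arg = xr.argmax(axis=-1)  # first maximum wins on ties
    out = np.take_along_axis(xr, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        gwin = np.zeros_like(xr)
        np.put_along_axis(gwin, arg[..., None], g[..., None], axis=-1)
        gx = (
            gwin.reshape(n, c, hw, ww, pool, pool)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )
        x._accumulate(gx)

    return Tensor._from_op(out, (x,), backward)


def _linear_interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Row-stochastic matrix realizing 1-D bilinear resampling
    (align_corners=False convention, edges clamped)."""
    a = np.zeros((n_out, n_in))
    scale = n_in / n_out
    for i in range(n_out):
        pos = (i + 0.5) * scale - 0.5
        lo = int(np.floor(pos))
        frac = pos - lo
        lo_c = min(max(lo, 0), n_in - 1)
        hi_c = min(max(lo + 1, 0), n_in - 1)
        a[i, lo_c] += 1.0 - frac
        a[i, hi_c] += frac
    return a


def upsample_bilinear2d(x: Tensor, scale: int) -> Tensor:
    """Bilinear upsampling by an integer scale factor, NCHW."""
    x = as_tensor(x)
    n, c, h, w = x.shape
    ah = _linear_interp_matrix(h * scale, h).astype(x.data.dtype)
    aw = _linear_interp_matrix(w * scale, w).astype(x.data.dtype)
    out = np.matmul(np.matmul(ah, x.data), aw.T)

    def backward(g):
        x._accumulate(np.matmul(np.matmul(ah.T, g), aw))

    return Tensor._from_op(out, (x,), backward)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = as_tensor(x)
    m = x.data.max(axis=axis, keepdims=True)
    z = x.data - m
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out = z - lse

    def backward(g):
        soft = np.exp(out)
        x._accumulate(g - soft * g.sum(axis=axis, keepdims=True))

    return Tensor._from_op(out, (x,), backward)


def overlap_add(frames: Tensor, hop: int, length: int) -> Tensor:
    """Overlap-add frames (T', nfft) into a signal of ``length`` samples."""
    frames = as_tensor(frames)
    n_frames, nfft = frames.shape
    idx = hop * np.arange(n_frames)[:, None] + np.arange(nfft)[None, :]
    if idx.max() >= length:
        raise ValueError("overlap_add: frames extend past the requested length")
    out = np.zeros(length, dtype=frames.data.dtype)
    np.add.at(out, idx, frames.data)

    def backward(g):
        frames._accumulate(g[idx])

    return Tensor._from_op(out, (frames,), backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return as_tensor(x)
    x = as_tensor(x)
    keep = rng.random(x.shape) >= p
    scale = 1.0 / (1.0 - p)
    out = x.data * keep * scale

    def backward(g):
        x._accumulate(g * keep * scale)

    return Tensor._from_op(out, (x,), backward)
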