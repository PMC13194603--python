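"""Low-level conv arithmetic on (N, C, H, W) arrays.

Convolutions are evaluated as a sum of kh*kw shifted GEMMs, which avoids
materializing the full im2col matrix and keeps every copy contiguous.  The
transposed convolution is implemented as the exact adjoint of the strided
convolution, so the two share their gradient structure.
"""

from __future__ import annotations

import numpy as np


def _out_size(size: int, k: int, stride: int) -> int:
    out = (size - k) // stride + 1
    if out < 1:
        raise ValueError(f"spatial size {size} smaller than kernel {k}")
    return out


def conv2d_forward(x, w, b, stride: int, pad: int):
    """y = conv(x, w) + b.  x (N,Ci,H,W), w (Co,Ci,kh,kw), b (Co,) or None."""
    co, ci, kh, kw = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    n, _, hp, wp = xp.shape
    oh = _out_size(hp, kh, stride)
    ow = _out_size(wp, kw, stride)
    acc = np.zeros((n * oh * ow, co), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            xs = xp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride]
            xm = xs.transpose(0, 2, 3, 1).reshape(-1, ci)
            acc += xm @ w[:, :, i, j].T
    if b is not None:
        acc += b
    y = acc.reshape(n, oh, ow, co).transpose(0, 3, 1, 2)
    return np.ascontiguousarray(y), xp


def conv2d_backward(dy, w, stride: int, pad: int, cache):
    """Returns (dx, dw, db) for :func:`conv2d_forward`."""
    xp = cache
    co, ci, kh, kw = w.shape
    n, _, oh, ow = dy.shape
    dy_mat = np.ascontiguousarray(dy.transpose(0, 2, 3, 1).reshape(-1, co))
    dw = np.empty_like(w, dtype=dy.dtype)
    dxp = np.zeros_like(xp, dtype=dy.dtype)
    for i in range(kh):
        for j in range(kw):
            sl = np.s_[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride]
            xm = xp[sl].transpose(0, 2, 3, 1).reshape(-1, ci)
            dw[:, :, i, j] = dy_mat.T @ xm
            dxs = (dy_mat @ w[:, :, i, j]).reshape(n, oh, ow, ci)
            dxp[sl] += dxs.transpose(0, 3, 1, 2)
    db = dy_mat.sum(axis=0)
    dx = dxp[:, :, pad:-pad, pad:-pad] if pad else dxp
    return np.ascontiguousarray(dx), dw, db


def conv_transpose2d_forward(x, w, b, stride: int, pad: int, output_pad: int):
    """Transposed conv (adjoint of the strided conv).  x (N,Ci,H,W),
    w (Ci,Co,kh,kw).  Output size: (H-1)*stride - 2*pad + kh + output_pad."""
    ci, co, kh, kw = w.shape
    n, _, h, wi = x.shape
    hc = (h - 1) * stride + kh
    wc = (wi - 1) * stride + kw
    x_mat = np.ascontiguousarray(x.transpose(0, 2, 3, 1).reshape(-1, ci))
    canvas = np.zeros((n, co, hc + output_pad, wc + output_pad), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            ys = (x_mat @ w[:, :, i, j]).reshape(n, h, wi, co)
            canvas[:, :, i : i + stride * h : stride, j : j + stride * wi : stride] += (
                ys.transpose(0, 3, 1, 2)
            )
    h_out = (h - 1) * stride - 2 * pad + kh + output_pad
    w_out = (wi - 1) * stride - 2 * pad + kw + output_pad
    y = canvas[:, :, pad : pad + h_out, pad : pad + w_out]
    if b is not None:
        y = y + b[None, :, None, None]
    return np.ascontiguousarray(y), (x_mat, x.shape, (hc, wc))


def conv_transpose2d_backward(dy, w, stride: int, pad: int, output_pad: int, cache):
    """Returns (dx, dw, db) for :func:`conv_transpose2d_forward`."""
    x_mat, x_shape, (hc, wc) = cache
    ci, co, kh, kw = w.shape
    n, _, h, wi = x_shape
    db = dy.sum(axis=(0, 2, 3))
    gcanvas = np.zeros((n, co, hc + output_pad, wc + output_pad), dtype=dy.dtype)
    h_out, w_out = dy.shape[2], dy.shape[3]
    gcanvas[:, :, pad : pad + h_out, pad : pad + w_out] = dy
    dx_mat = np.zeros_like(x_mat, dtype=dy.dtype)
    dw = np.empty_like(w, dtype=dy.dtype)
    for i in range(kh):
        for j in range(kw):
            gs = gcanvas[:, :, i : i + stride * h : stride, j : j + stride * wi : stride]
            gm = gs.transpose(0, 2, 3, 1).reshape(-1, co)
            dx_mat += gm @ w[:, :, i, j].T
            dw[:, :, i, j] = x_mat.T @ gm
    dx = dx_mat.reshape(n, h, wi, ci).transpose(0, 3, 1, 2)
    return np.ascontiguousarray(dx), dw, db
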