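"""Convolution, transposed convolution, instance norm and patch ops.

Convolutions run as im2col + GEMM; the input gradient is computed with the
zero-stuffed / flipped-kernel identity so every backward path is also a GEMM
(no scatter loops on the hot path).  Padding may be asymmetric,
``(top, bottom, left, right)``, which the PatchGAN discriminator needs for
its size-preserving stride-1 4x4 layers.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor


def _norm_pad(pad) -> tuple[int, int, int, int]:
    if isinstance(pad, int):
        return (pad, pad, pad, pad)
    if len(pad) == 2:
        return (pad[0], pad[0], pad[1], pad[1])
    return tuple(pad)


def _pad_zeros(x: np.ndarray, pad: tuple[int, int, int, int]) -> np.ndarray:
    t, b, l, r = pad
    if t == b == l == r == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (t, b), (l, r)))


def _im2col(xp: np.ndarray, kh: int, kw: int, sh: int, sw: int):
    """(N, C, Hp, Wp) -> (N, Ho*Wo, C*kh*kw) patch matrix (attention only;
    the conv hot path uses the offset-GEMM kernels below)."""
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # N,C,Ho',Wo',kh,kw
    win = win[:, :, ::sh, ::sw]
    n, c, ho, wo = win.shape[:4]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * kh * kw)
    return np.ascontiguousarray(cols), ho, wo


def _offset_slice(xp, dy, dx, sh, sw, ho, wo):
    """(Cin, N*Ho*Wo) matrix of the input pixels kernel tap (dy, dx) sees."""
    sl = xp[:, :, dy:dy + sh * (ho - 1) + 1:sh, dx:dx + sw * (wo - 1) + 1:sw]
    c = sl.shape[1]
    return sl.transpose(1, 0, 2, 3).reshape(c, -1)


def _conv_forward(x, w, stride, pad):
    """x (N,Cin,H,W), w (Cout,Cin,kh,kw) -> (y, padded input).

    One (Cout, Cin) GEMM per kernel offset on contiguous slices — faster
    than im2col for the small channel counts this package runs at, and
    without im2col's k^2-fold memory inflation for the 7x7 layers.
    """
    sh, sw = (stride, stride) if isinstance(stride, int) else stride
    cout, cin, kh, kw = w.shape
    xp = _pad_zeros(x, pad)
    n, _, hp, wp = xp.shape
    ho = (hp - kh) // sh + 1
    wo = (wp - kw) // sw + 1
    yf = np.zeros((cout, n * ho * wo), dtype=np.float32)
    for dy in range(kh):
        for dx in range(kw):
            yf += w[:, :, dy, dx] @ _offset_slice(xp, dy, dx, sh, sw, ho, wo)
    y = yf.reshape(cout, n, ho, wo).transpose(1, 0, 2, 3)
    return np.ascontiguousarray(y), xp


def _conv_input_grad(gy, w, stride, pad, x_shape):
    """Gradient of conv wrt its input: scatter each offset's (Cin, Cout)
    GEMM back onto the padded input frame."""
    sh, sw = (stride, stride) if isinstance(stride, int) else stride
    n, cout, ho, wo = gy.shape
    cin, kh, kw = w.shape[1], w.shape[2], w.shape[3]
    t, b, l, r = pad
    hp, wp = x_shape[2] + t + b, x_shape[3] + l + r
    gym = np.ascontiguousarray(gy.transpose(1, 0, 2, 3)).reshape(cout, -1)
    gxp = np.zeros((cin, n, hp, wp), dtype=np.float32)
    for dy in range(kh):
        for dx in range(kw):
            block = (w[:, :, dy, dx].T @ gym).reshape(cin, n, ho, wo)
            gxp[:, :, dy:dy + sh * (ho - 1) + 1:sh,
                dx:dx + sw * (wo - 1) + 1:sw] += block
    gx = gxp[:, :, t:t + x_shape[2], l:l + x_shape[3]].transpose(1, 0, 2, 3)
    return np.ascontiguousarray(gx)


def _conv_weight_grad(xp, gy, w_shape, stride):
    sh, sw = (stride, stride) if isinstance(stride, int) else stride
    n, cout, ho, wo = gy.shape
    cout_w, cin, kh, kw = w_shape
    gym = np.ascontiguousarray(gy.transpose(1, 0, 2, 3)).reshape(cout, -1)
    gw = np.empty(w_shape, dtype=np.float32)
    for dy in range(kh):
        for dx in range(kw):
            gw[:, :, dy, dx] = gym @ _offset_slice(xp, dy, dx, sh, sw,
                                                   ho, wo).T
    return gw


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride=1, pad=0) -> Tensor:
    pad = _norm_pad(pad)
    y, xp = _conv_forward(x.data, w.data, stride, pad)
    if b is not None:
        y = y + b.data.reshape(1, -1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        if x.requires_grad:
            x._accumulate(_conv_input_grad(g, w.data, stride, pad, x.data.shape))
        if w.requires_grad:
            w._accumulate(_conv_weight_grad(xp, g, w.data.shape, stride))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    return Tensor._make(y, parents, backward)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None,
                     stride=2, pad=1) -> Tensor:
    """w has shape (Cin, Cout, kh, kw); output size (H-1)*s - 2p + k."""
    pad4 = _norm_pad(pad)
    sh = stride if isinstance(stride, int) else stride[0]
    n, cin, h, wd = x.data.shape
    _, cout, kh, kw = w.data.shape
    out_h = (h - 1) * sh - (pad4[0] + pad4[1]) + kh
    out_w = (wd - 1) * sh - (pad4[2] + pad4[3]) + kw
    # transposed conv is the adjoint of conv(stride, pad) with weight w
    # viewed as (Cin->Cout); reuse the conv input-gradient kernel
    y = _conv_input_grad(x.data, w.data, (sh, sh), pad4,
                         (n, cout, out_h, out_w))
    if b is not None:
        y = y + b.data.reshape(1, -1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        if x.requires_grad:
            gx, _ = _conv_forward(g, w.data, (sh, sh), pad4)
            x._accumulate(gx)
        if w.requires_grad:
            gp = _pad_zeros(g, pad4)
            gw = _conv_weight_grad(gp, x.data, (cin, cout, kh, kw), (sh, sh))
            w._accumulate(gw)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    return Tensor._make(y, parents, backward)


def instance_norm(x: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel normalization over the spatial axes."""
    mu = x.data.mean(axis=(2, 3), keepdims=True)
    var = x.data.var(axis=(2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    y = (x.data - mu) * inv

    def backward(g):
        if not x.requires_grad:
            return
        m = x.data.shape[2] * x.data.shape[3]
        gmean = g.mean(axis=(2, 3), keepdims=True)
        gymean = (g * y).mean(axis=(2, 3), keepdims=True)
        x._accumulate(inv * (g - gmean - y * gymean))

    return Tensor._make(y.astype(np.float32), (x,), backward)


def spectral_normalize(w: Tensor, u: np.ndarray, update: bool = True,
                       eps: float = 1e-12) -> Tensor:
    """Divide ``w`` by its leading singular value, estimated by one power
    iteration on the (Cout, -1) matricization.  ``u`` is a persistent buffer
    updated in place when ``update`` is true."""
    wm = w.data.reshape(w.data.shape[0], -1)
    if update:
        v = wm.T @ u
        v = v / (np.linalg.norm(v) + eps)
        u_new = wm @ v
        u_new = u_new / (np.linalg.norm(u_new) + eps)
        u[:] = u_new
    v = wm.T @ u
    v = v / (np.linalg.norm(v) + eps)
    sigma = float(u @ (wm @ v))
    sigma = max(sigma, eps)
    wbar = w.data / sigma
    uvT = np.outer(u, v).reshape(w.data.shape)

    def backward(g):
        if w.requires_grad:
            w._accumulate(g / sigma - (np.sum(g * wbar) / sigma) * uvT)

    return Tensor._make(wbar, (w,), backward)


def unfold(x: Tensor, k: int, pad: int = 0) -> Tensor:
    """Extract all k x k patches (stride 1) -> (N, H*W, C*k*k)."""
    pad4 = (pad, pad, pad, pad)
    xp = _pad_zeros(x.data, pad4)
    cols, ho, wo = _im2col(xp, k, k, 1, 1)

    def backward(g):
        if not x.requires_grad:
            return
        n, c = x.data.shape[:2]
        # adjoint of im2col: a transposed conv of the patch grid with
        # identity kernels; done directly with the conv input-grad kernel
        gy = g.reshape(n, ho, wo, c, k, k).transpose(0, 3, 4, 5, 1, 2)
        gy = gy.reshape(n, c * k * k, ho, wo)
        eye = np.zeros((c * k * k, c, k, k), dtype=np.float32)
        idx = np.arange(c * k * k)
        eye[idx, idx // (k * k), (idx % (k * k)) // k, idx % k] = 1.0
        gx = _conv_input_grad(gy, eye, (1, 1), pad4, x.data.shape)
        x._accumulate(gx)

    return Tensor._make(cols, (x,), backward)
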