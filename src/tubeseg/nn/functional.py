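"""Custom differentiable primitives for volumetric networks.

Layouts follow the (N, C, X, Y, Z) convention. Convolution is computed by
looping over kernel offsets — one (Cout, Cin) x (Cin, P) matmul per offset —
which keeps memory flat compared to a full im2col buffer while still
running through BLAS.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, is_grad_enabled


def _same_padding(kernel: int, dilation: int) -> int:
    return dilation * (kernel - 1) // 2


def conv3d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None,
    stride: int = 1,
    dilation: int = 1,
    padding: int | None = None,
) -> Tensor:
    """3D cross-correlation with same-style padding by default.

    weight: (Cout, Cin, kx, ky, kz); odd kernels only. With stride 1 and the
    default padding the spatial extent is preserved for any dilation.
    """
    cout, cin, kx, ky, kz = weight.shape
    if x.shape[1] != cin:
        raise ValueError(
            f"conv3d: input has {x.shape[1]} channels, weight expects {cin}"
        )
    if padding is None:
        pads = tuple(_same_padding(k, dilation) for k in (kx, ky, kz))
    else:
        pads = (padding, padding, padding)
    n = x.shape[0]
    xp = np.pad(
        x.data,
        ((0, 0), (0, 0), (pads[0],) * 2, (pads[1],) * 2, (pads[2],) * 2),
    )
    sx, sy, sz = xp.shape[2:]
    ox = (sx - dilation * (kx - 1) - 1) // stride + 1
    oy = (sy - dilation * (ky - 1) - 1) // stride + 1
    oz = (sz - dilation * (kz - 1) - 1) // stride + 1
    if min(ox, oy, oz) < 1:
        raise ValueError("conv3d: kernel does not fit in padded input")
    p = ox * oy * oz
    w2 = weight.data.reshape(cout, cin, -1)
    out = np.zeros((n, cout, p), dtype=np.float32)
    views = []
    k = 0
    for ax in range(kx):
        for ay in range(ky):
            for az in range(kz):
                v = xp[
                    :,
                    :,
                    ax * dilation : ax * dilation + (ox - 1) * stride + 1 : stride,
                    ay * dilation : ay * dilation + (oy - 1) * stride + 1 : stride,
                    az * dilation : az * dilation + (oz - 1) * stride + 1 : stride,
                ]
                v = np.ascontiguousarray(v).reshape(n, cin, p)
                views.append(v)
                out += np.matmul(w2[:, :, k], v)
                k += 1
    if bias is not None:
        out += bias.data.reshape(1, cout, 1)
    out = out.reshape(n, cout, ox, oy, oz)

    needs_grad = is_grad_enabled() and (
        x.requires_grad or weight.requires_grad or (bias is not None and bias.requires_grad)
    )
    if not needs_grad:
        return Tensor(out)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def bwd(g):
        gf = g.reshape(n, cout, p)
        if bias is not None and bias.requires_grad:
            bias._accum(gf.sum(axis=(0, 2)))
        if weight.requires_grad:
            dw = np.empty_like(weight.data.reshape(cout, cin, -1))
            for kk, v in enumerate(views):
                # sum over batch and spatial positions
                dw[:, :, kk] = np.einsum("nop,ncp->oc", gf, v, optimize=True)
            weight._accum(dw.reshape(weight.shape))
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            kk = 0
            for ax in range(kx):
                for ay in range(ky):
                    for az in range(kz):
                        dv = np.matmul(w2[:, :, kk].T, gf).reshape(n, cin, ox, oy, oz)
                        dxp[
                            :,
                            :,
                            ax * dilation : ax * dilation + (ox - 1) * stride + 1 : stride,
                            ay * dilation : ay * dilation + (oy - 1) * stride + 1 : stride,
                            az * dilation : az * dilation + (oz - 1) * stride + 1 : stride,
                        ] += dv
                        kk += 1
            px, py, pz = pads
            dx = dxp[
                :,
                :,
                px : px + x.shape[2],
                py : py + x.shape[3],
                pz : pz + x.shape[4],
            ]
            x._accum(dx)

    return Tensor._make(out, parents, bwd)


def instance_norm3d(
    x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5
) -> Tensor:
    """Per-(sample, channel) normalization over the spatial axes, affine."""
    axes = (2, 3, 4)
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    gshape = (1, -1, 1, 1, 1)
    out = xhat * gamma.data.reshape(gshape) + beta.data.reshape(gshape)

    def bwd(g):
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, 2, 3, 4)))
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=(0, 2, 3, 4)))
        if x.requires_grad:
            gy = g * gamma.data.reshape(gshape)
            m1 = gy.mean(axis=axes, keepdims=True)
            m2 = (gy * xhat).mean(axis=axes, keepdims=True)
            x._accum(inv * (gy - m1 - xhat * m2))

    return Tensor._make(out, (x, gamma, beta), bwd)


def _upsample_axis_indices(n: int):
    """Length-2n index/weight arrays for x2 linear upsampling of one axis.

    Output sample o sits at source coordinate o/2 - 0.25 (half-pixel
    centers), i.e. a fixed 0.75/0.25 stencil with edge clamping.
    """
    o = np.arange(2 * n)
    src = o / 2.0 - 0.25
    i0 = np.floor(src).astype(np.int64)
    w1 = (src - i0).astype(np.float32)
    w0 = 1.0 - w1
    i1 = np.clip(i0 + 1, 0, n - 1)
    i0 = np.clip(i0, 0, n - 1)
    return i0, i1, w0, w1


def _upsample_one_axis(a: np.ndarray, axis: int) -> np.ndarray:
    n = a.shape[axis]
    i0, i1, w0, w1 = _upsample_axis_indices(n)
    t0 = np.take(a, i0, axis=axis)
    t1 = np.take(a, i1, axis=axis)
    shape = [1] * a.ndim
    shape[axis] = 2 * n
    return t0 * w0.reshape(shape) + t1 * w1.reshape(shape)


def _downsample_adjoint_one_axis(g: np.ndarray, axis: int, n: int) -> np.ndarray:
    i0, i1, w0, w1 = _upsample_axis_indices(n)
    gm = np.moveaxis(g, axis, 0)
    shape = [1] * gm.ndim
    shape[0] = 2 * n
    out = np.zeros((n,) + gm.shape[1:], dtype=np.float32)
    np.add.at(out, i0, gm * w0.reshape(shape))
    np.add.at(out, i1, gm * w1.reshape(shape))
    return np.moveaxis(out, 0, axis)


def upsample_trilinear2x(x: Tensor) -> Tensor:
    """Double every spatial dimension by separable linear interpolation."""
    y = x.data
    for axis in (2, 3, 4):
        y = _upsample_one_axis(y, axis)
    y = y.astype(np.float32)

    def bwd(g):
        d = g
        for axis in (4, 3, 2):
            d = _downsample_adjoint_one_axis(d, axis, x.shape[axis])
        x._accum(d)

    return Tensor._make(y, (x,), bwd)


def dropout(x: Tensor, p: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; caller is responsible for skipping it at eval."""
    if p <= 0.0:
        return x
    keep = (rng.random(x.shape) >= p).astype(np.float32) / (1.0 - p)

    def bwd(g):
        x._accum(g * keep)

    return Tensor._make(x.data * keep, (x,), bwd)
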