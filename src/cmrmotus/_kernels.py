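"""Numba kernels for B-spline warping (gather / scatter / derivative gather).

All kernels operate on frame stacks ``(M, ny, nx)``.  Sample positions are
``(px, py)`` in voxel coordinates; B-spline coefficients outside the grid are
zero, so out-of-range taps simply do not contribute.  ``scatter1`` is the exact
adjoint of ``gather1`` by construction (same taps, same weights).
"""

from __future__ import annotations

import numba as nb
import numpy as np


@nb.njit(inline="always", cache=True)
def _weights(t):
    w0 = (1.0 - t) ** 3 / 6.0
    w1 = 2.0 / 3.0 - t * t + 0.5 * t * t * t
    w2 = (1.0 + 3.0 * t + 3.0 * t * t - 3.0 * t * t * t) / 6.0
    w3 = t * t * t / 6.0
    return w0, w1, w2, w3


@nb.njit(inline="always", cache=True)
def _dweights(t):
    d0 = -0.5 * (1.0 - t) ** 2
    d1 = -2.0 * t + 1.5 * t * t
    d2 = 0.5 + t - 1.5 * t * t
    d3 = 0.5 * t * t
    return d0, d1, d2, d3


@nb.njit(cache=True)
def thomas2(a, cpx, cpy):
    """In-place symmetric tridiagonal solves ([1/6, 2/3, 1/6]) along x then y.

    ``cpx`` / ``cpy`` are the precomputed forward-sweep coefficients for the
    respective axis lengths; the result equals the banded solve of the cubic
    B-spline interpolation system with Dirichlet boundary.
    """
    M, ny, nx = a.shape
    b = 2.0 / 3.0
    s = 1.0 / 6.0
    for m in range(M):
        for i in range(ny):
            a[m, i, 0] = a[m, i, 0] / b
            for j in range(1, nx):
                a[m, i, j] = (a[m, i, j] - s * a[m, i, j - 1]) / (b - s * cpx[j - 1])
            for j in range(nx - 2, -1, -1):
                a[m, i, j] = a[m, i, j] - cpx[j] * a[m, i, j + 1]
        for j in range(nx):
            a[m, 0, j] = a[m, 0, j] / b
        for i in range(1, ny):
            denom = b - s * cpy[i - 1]
            for j in range(nx):
                a[m, i, j] = (a[m, i, j] - s * a[m, i - 1, j]) / denom
        for i in range(ny - 2, -1, -1):
            for j in range(nx):
                a[m, i, j] = a[m, i, j] - cpy[i] * a[m, i + 1, j]
    return a


@nb.njit(cache=True)
def gather1(coef, px, py, out):
    """out[t, i, j] = sum_kl B3 weights * coef[t, ...] at (px, py)."""
    M, ny, nx = out.shape
    for t in range(M):
        for i in range(ny):
            for j in range(nx):
                x = px[t, i, j]
                y = py[t, i, j]
                acc = coef[0, 0, 0] * 0.0
                if -2.0 < x < nx + 1.0 and -2.0 < y < ny + 1.0:
                    bx = int(np.floor(x))
                    by = int(np.floor(y))
                    wx0, wx1, wx2, wx3 = _weights(x - bx)
                    wy0, wy1, wy2, wy3 = _weights(y - by)
                    wxs = (wx0, wx1, wx2, wx3)
                    wys = (wy0, wy1, wy2, wy3)
                    for l in range(4):
                        yy = by - 1 + l
                        if yy < 0 or yy >= ny:
                            continue
                        wy = wys[l]
                        for k in range(4):
                            xx = bx - 1 + k
                            if xx < 0 or xx >= nx:
                                continue
                            acc += wys[l] * wxs[k] * coef[t, yy, xx]
                out[t, i, j] = acc
    return out


@nb.njit(cache=True)
def gather3(coef, px, py, out, outx, outy):
    """Value and spatial derivatives of the spline at (px, py)."""
    M, ny, nx = out.shape
    for t in range(M):
        for i in range(ny):
            for j in range(nx):
                x = px[t, i, j]
                y = py[t, i, j]
                acc = coef[0, 0, 0] * 0.0
                accx = acc
                accy = acc
                if -2.0 < x < nx + 1.0 and -2.0 < y < ny + 1.0:
                    bx = int(np.floor(x))
                    by = int(np.floor(y))
                    tx = x - bx
                    ty = y - by
                    wx = _weights(tx)
                    wy = _weights(ty)
                    dwx = _dweights(tx)
                    dwy = _dweights(ty)
                    for l in range(4):
                        yy = by - 1 + l
                        if yy < 0 or yy >= ny:
                            continue
                        for k in range(4):
                            xx = bx - 1 + k
                            if xx < 0 or xx >= nx:
                                continue
                            c = coef[t, yy, xx]
                            acc += wy[l] * wx[k] * c
                            accx += wy[l] * dwx[k] * c
                            accy += dwy[l] * wx[k] * c
                out[t, i, j] = acc
                outx[t, i, j] = accx
                outy[t, i, j] = accy
    return out


@nb.njit(inline="always", cache=True)
def _gx_at(f, i, j, nx):
    if j == 0:
        return f[i, 1] - f[i, 0]
    if j == nx - 1:
        return f[i, nx - 1] - f[i, nx - 2]
    return 0.5 * (f[i, j + 1] - f[i, j - 1])


@nb.njit(inline="always", cache=True)
def _gy_at(f, i, j, ny):
    if i == 0:
        return f[1, j] - f[0, j]
    if i == ny - 1:
        return f[ny - 1, j] - f[ny - 2, j]
    return 0.5 * (f[i + 1, j] - f[i - 1, j])


@nb.njit(cache=True)
def warp_prep(d, xg, yg, px, py, det):
    """Sample positions r + D and det of the Jacobian (centered differences)."""
    M, _, ny, nx = d.shape
    for m in range(M):
        d0 = d[m, 0]
        d1 = d[m, 1]
        for i in range(ny):
            for j in range(nx):
                px[m, i, j] = xg[i, j] + d0[i, j]
                py[m, i, j] = yg[i, j] + d1[i, j]
                d0x = _gx_at(d0, i, j, nx)
                d0y = _gy_at(d0, i, j, ny)
                d1x = _gx_at(d1, i, j, nx)
                d1y = _gy_at(d1, i, j, ny)
                det[m, i, j] = (1.0 + d0x) * (1.0 + d1y) - d0y * d1x
    return det


@nb.njit(inline="always", cache=True)
def _scatter_gx_T(out, i, j, nx, v):
    if j == 0:
        out[i, 0] -= v
        out[i, 1] += v
    elif j == nx - 1:
        out[i, nx - 2] -= v
        out[i, nx - 1] += v
    else:
        out[i, j + 1] += 0.5 * v
        out[i, j - 1] -= 0.5 * v


@nb.njit(inline="always", cache=True)
def _scatter_gy_T(out, i, j, ny, v):
    if i == 0:
        out[0, j] -= v
        out[1, j] += v
    elif i == ny - 1:
        out[ny - 2, j] -= v
        out[ny - 1, j] += v
    else:
        out[i + 1, j] += 0.5 * v
        out[i - 1, j] -= 0.5 * v


@nb.njit(cache=True)
def det_chain(e, gx, gy, w0, d, det, g_d):
    """Gradient of the data term w.r.t. the dense fields.

    ``e`` is the adjoint image of the residual; the warp is
    ``w = interp(r + D) * det``, so the gradient has an interpolation part
    (``det * 2 Re(conj(e) grad interp)``) and a determinant part obtained by
    the exact transposes of the finite-difference stencils.
    """
    M, _, ny, nx = d.shape
    for m in range(M):
        d0 = d[m, 0]
        d1 = d[m, 1]
        o0 = g_d[m, 0]
        o1 = g_d[m, 1]
        for i in range(ny):
            for j in range(nx):
                ere = e[m, i, j].real
                eim = e[m, i, j].imag
                o0[i, j] = det[m, i, j] * 2.0 * (
                    ere * gx[m, i, j].real + eim * gx[m, i, j].imag
                )
                o1[i, j] = det[m, i, j] * 2.0 * (
                    ere * gy[m, i, j].real + eim * gy[m, i, j].imag
                )
        for i in range(ny):
            for j in range(nx):
                t0 = 2.0 * (
                    e[m, i, j].real * w0[m, i, j].real
                    + e[m, i, j].imag * w0[m, i, j].imag
                )
                d0x = _gx_at(d0, i, j, nx)
                d0y = _gy_at(d0, i, j, ny)
                d1x = _gx_at(d1, i, j, nx)
                d1y = _gy_at(d1, i, j, ny)
                _scatter_gx_T(o0, i, j, nx, t0 * (1.0 + d1y))
                _scatter_gy_T(o0, i, j, ny, -t0 * d1x)
                _scatter_gy_T(o1, i, j, ny, t0 * (1.0 + d0x))
                _scatter_gx_T(o1, i, j, nx, -t0 * d0y)
    return g_d


@nb.njit(cache=True)
def tv_mixed21_grad(d, eps, lam, g_d):
    """Isotropic per-component TV: exact value, smoothed gradient added in place.

    Forward differences with zero-flux boundary; gradient smoothing ``eps``
    affects only the gradient, not the returned value.
    """
    M, _, ny, nx = d.shape
    total = 0.0
    for m in range(M):
        for c in range(2):
            f = d[m, c]
            o = g_d[m, c]
            for i in range(ny):
                for j in range(nx):
                    fx = f[i, j + 1] - f[i, j] if j < nx - 1 else 0.0
                    fy = f[i + 1, j] - f[i, j] if i < ny - 1 else 0.0
                    mag2 = fx * fx + fy * fy
                    total += np.sqrt(mag2)
                    s = lam / np.sqrt(mag2 + eps * eps)
                    gxv = fx * s
                    gyv = fy * s
                    o[i, j] -= gxv + gyv
                    if j < nx - 1:
                        o[i, j + 1] += gxv
                    if i < ny - 1:
                        o[i + 1, j] += gyv
    return total


@nb.njit(cache=True)
def scatter1(px, py, vals, out):
    """Adjoint of :func:`gather1`: out[t, yy, xx] += w * vals[t, i, j]."""
    M, ny, nx = vals.shape
    for t in range(M):
        for i in range(ny):
            for j in range(nx):
                x = px[t, i, j]
                y = py[t, i, j]
                if not (-2.0 < x < nx + 1.0 and -2.0 < y < ny + 1.0):
                    continue
                v = vals[t, i, j]
                bx = int(np.floor(x))
                by = int(np.floor(y))
                wx = _weights(x - bx)
                wy = _weights(y - by)
                for l in range(4):
                    yy = by - 1 + l
                    if yy < 0 or yy >= ny:
                        continue
                    for k in range(4):
                        xx = bx - 1 + k
                        if xx < 0 or xx >= nx:
                            continue
                        out[t, yy, xx] += wy[l] * wx[k] * v
    return out
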