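"""Cubic B-spline bases: interpolation prefilter and control-grid expansion.

Interpolation follows the classic two-step scheme: an image ``q`` sampled on the
voxel grid is first converted to B-spline coefficients ``c`` by solving the
tridiagonal interpolation system (Dirichlet boundary: coefficients are zero
outside the grid, so the interpolant decays to zero outside the field of view),
after which values anywhere are tensor products of the cubic kernel

    B3(u) = 2/3 - u^2 + |u|^3/2        for |u| < 1
          = (2 - |u|)^3 / 6            for 1 <= |u| < 2.

The prefilter matrix is symmetric, so it is its own adjoint; the kernel
application is a sparse gather whose adjoint is the corresponding scatter
(see :mod:`cmrmotus._kernels`).
"""

from __future__ import annotations

import numpy as np
import scipy.linalg
import scipy.sparse

__all__ = [
    "prefilter",
    "bspline_basis_matrix",
    "bspline_kernel",
    "bspline_kernel_derivative",
]


def bspline_kernel(u: np.ndarray) -> np.ndarray:
    """Cubic B-spline kernel B3 evaluated at ``u``."""
    u = np.abs(np.asarray(u, dtype=np.float64))
    out = np.zeros_like(u)
    m1 = u < 1
    m2 = (u >= 1) & (u < 2)
    out[m1] = 2.0 / 3.0 - u[m1] ** 2 + 0.5 * u[m1] ** 3
    out[m2] = (2.0 - u[m2]) ** 3 / 6.0
    return out


def bspline_kernel_derivative(u: np.ndarray) -> np.ndarray:
    """Derivative of the cubic B-spline kernel."""
    u = np.asarray(u, dtype=np.float64)
    a = np.abs(u)
    s = np.sign(u)
    out = np.zeros_like(u)
    m1 = a < 1
    m2 = (a >= 1) & (a < 2)
    out[m1] = s[m1] * (-2.0 * a[m1] + 1.5 * a[m1] ** 2)
    out[m2] = s[m2] * (-0.5 * (2.0 - a[m2]) ** 2)
    return out


def _banded(n: int) -> np.ndarray:
    ab = np.zeros((3, n))
    ab[0, 1:] = 1.0 / 6.0
    ab[1, :] = 2.0 / 3.0
    ab[2, :-1] = 1.0 / 6.0
    return ab


def _thomas_coeffs(n: int) -> np.ndarray:
    cp = np.empty(n, dtype=np.float64)
    b, s = 2.0 / 3.0, 1.0 / 6.0
    cp[0] = s / b
    for i in range(1, n):
        cp[i] = s / (b - s * cp[i - 1])
    return cp


def prefilter(stack: np.ndarray) -> np.ndarray:
    """Convert images to interpolating B-spline coefficients.

    Operates on the last two axes of ``stack`` (any number of leading axes).
    The operation is linear and self-adjoint.
    """
    stack = np.asarray(stack)
    if stack.ndim == 3 and stack.flags.c_contiguous and stack.dtype in (
        np.dtype(np.float32), np.dtype(np.float64),
        np.dtype(np.complex64), np.dtype(np.complex128),
    ):
        from . import _kernels

        out = stack.copy()
        ny, nx = stack.shape[-2:]
        _kernels.thomas2(out, _thomas_coeffs(nx), _thomas_coeffs(ny))
        return out
    shape = stack.shape
    ny, nx = shape[-2], shape[-1]
    # solve along y (rows axis)
    a = stack.reshape(-1, ny, nx)
    a = np.moveaxis(a, 1, 0).reshape(ny, -1)
    a = scipy.linalg.solve_banded((1, 1), _banded(ny), a)
    a = np.moveaxis(a.reshape(ny, -1, nx), 0, 1)
    # solve along x (columns axis)
    a = np.moveaxis(a, 2, 0).reshape(nx, -1)
    a = scipy.linalg.solve_banded((1, 1), _banded(nx), a)
    a = np.moveaxis(a.reshape(nx, -1, ny), 0, 2)
    return np.ascontiguousarray(a.reshape(shape)).astype(stack.dtype, copy=False)


def bspline_basis_matrix(n: int, n_ctrl: int) -> scipy.sparse.csr_matrix:
    """Sparse ``(n, n_ctrl)`` cubic B-spline design matrix on ``[0, n-1]``.

    Control points are uniformly spaced with spacing ``(n-1)/(n_ctrl-3)`` so that
    every sample lies in the full support of four basis functions (free-form
    deformation layout).  Rows sum to one (partition of unity).
    """
    if n_ctrl < 4:
        raise ValueError("need at least 4 control points")
    if n_ctrl > n:
        raise ValueError("control count exceeds grid size")
    h = (n - 1) / (n_ctrl - 3)
    x = np.arange(n, dtype=np.float64)
    u = x / h + 1.0
    base = np.floor(u).astype(int)
    base = np.clip(base, 1, n_ctrl - 3)  # guard the right endpoint u == n_ctrl-2
    rows, cols, vals = [], [], []
    for off in range(-1, 3):
        idx = base + off
        w = bspline_kernel(u - idx)
        rows.append(np.arange(n))
        cols.append(idx)
        vals.append(w)
    mat = scipy.sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n_ctrl),
    )
    return mat
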