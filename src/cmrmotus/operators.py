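"""Linear and nonlinear building blocks of the signal model.

The forward model for frame ``t`` factorizes as

    s_t = Mask_t . FFT . CoilMult . Warp(q_t, D_t)

where the warp is the pull-back ``q_t(r + D_t(r))`` (cubic B-spline
interpolation, zero outside the field of view) multiplied by the determinant of
the Jacobian of ``r -> r + D_t(r)``, so that integrated intensity (magnetization)
is conserved under deformation.  With ``D = 0`` the model reduces to a plain
masked coil-weighted Fourier transform.

Every operator here has an exact adjoint: the FFT is unitary, the coil
multiplication adjoint is the conjugate multiplication, and the warp adjoint is
the scatter transpose of the interpolation gather (including the determinant
weighting and the self-adjoint prefilter).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np
import scipy.fft
import scipy.sparse

from . import _kernels
from .bspline import bspline_basis_matrix, prefilter
from .containers import CoilMaps, DynamicKSpace, ImageGrid, MotionFieldStack

__all__ = [
    "LowRankMotionModel",
    "expand_motion",
    "warp_image",
    "warp_image_adjoint",
    "WarpGeometry",
    "forward_signal",
    "adjoint_signal",
    "MotionConditionalOperator",
    "temporal_fourier",
    "temporal_fourier_adjoint",
    "spectral_norm",
    "fft2c",
    "ifft2c",
]


# ----------------------------------------------------------------------------
# FFT and finite-difference helpers
# ----------------------------------------------------------------------------

def fft2c(x: np.ndarray) -> np.ndarray:
    """Unitary 2D FFT over the last two axes (natural frequency ordering)."""
    return scipy.fft.fft2(x, norm="ortho")


def ifft2c(x: np.ndarray) -> np.ndarray:
    return scipy.fft.ifft2(x, norm="ortho")


def grad_x(f: np.ndarray) -> np.ndarray:
    """Centered difference along x (last axis), one-sided at the edges."""
    g = np.empty_like(f)
    g[..., 1:-1] = 0.5 * (f[..., 2:] - f[..., :-2])
    g[..., 0] = f[..., 1] - f[..., 0]
    g[..., -1] = f[..., -1] - f[..., -2]
    return g


def grad_y(f: np.ndarray) -> np.ndarray:
    g = np.empty_like(f)
    g[..., 1:-1, :] = 0.5 * (f[..., 2:, :] - f[..., :-2, :])
    g[..., 0, :] = f[..., 1, :] - f[..., 0, :]
    g[..., -1, :] = f[..., -1, :] - f[..., -2, :]
    return g


def grad_x_T(y: np.ndarray) -> np.ndarray:
    """Exact transpose of :func:`grad_x`."""
    x = np.zeros_like(y)
    x[..., 2:] += 0.5 * y[..., 1:-1]
    x[..., :-2] -= 0.5 * y[..., 1:-1]
    x[..., 0] -= y[..., 0]
    x[..., 1] += y[..., 0]
    x[..., -2] -= y[..., -1]
    x[..., -1] += y[..., -1]
    return x


def grad_y_T(y: np.ndarray) -> np.ndarray:
    x = np.zeros_like(y)
    x[..., 2:, :] += 0.5 * y[..., 1:-1, :]
    x[..., :-2, :] -= 0.5 * y[..., 1:-1, :]
    x[..., 0, :] -= y[..., 0, :]
    x[..., 1, :] += y[..., 0, :]
    x[..., -2, :] -= y[..., -1, :]
    x[..., -1, :] += y[..., -1, :]
    return x


def jacobian_det(d: np.ndarray) -> np.ndarray:
    """det of the Jacobian of ``r -> r + D(r)`` from finite differences.

    ``d`` has shape ``(..., 2, ny, nx)`` (x-displacement first).
    """
    d0 = d[..., 0, :, :]
    d1 = d[..., 1, :, :]
    return (1.0 + grad_x(d0)) * (1.0 + grad_y(d1)) - grad_y(d0) * grad_x(d1)


# ----------------------------------------------------------------------------
# Low-rank B-spline motion model
# ----------------------------------------------------------------------------

@lru_cache(maxsize=32)
def _basis_1d(n: int, n_ctrl: int) -> scipy.sparse.csr_matrix:
    return bspline_basis_matrix(n, n_ctrl)


@lru_cache(maxsize=16)
def _basis_2d(ny: int, nx: int, n_ctrl: int) -> scipy.sparse.csr_matrix:
    by = _basis_1d(ny, n_ctrl)
    bx = _basis_1d(nx, n_ctrl)
    return scipy.sparse.kron(by, bx, format="csr")


@dataclass
class LowRankMotionModel:
    """Explicit-rank motion model ``D ~ Phi Psi^T`` on B-spline control grids.

    ``phi_c`` holds spatial control coefficients of shape
    ``(2, n_ctrl, n_ctrl, rank)`` (x-displacement component first) and ``psi_c``
    temporal coefficients of shape ``(n_tctrl, rank)``, or ``(M, rank)`` when the
    temporal B-spline is disabled (``temporal_controls is None``), in which case
    rows map one-to-one to frames.  Expansion to dense fields uses cubic
    tensor-product B-splines in space and (optionally) time.
    """

    grid: ImageGrid
    n_frames: int
    phi_c: np.ndarray
    psi_c: np.ndarray
    spatial_controls: int
    temporal_controls: Optional[int] = None

    def __post_init__(self) -> None:
        nc = self.spatial_controls
        if self.phi_c.shape != (2, nc, nc, self.rank):
            raise ValueError("phi_c must have shape (2, n_ctrl, n_ctrl, rank)")
        nt = self.temporal_controls if self.temporal_controls is not None else self.n_frames
        if self.psi_c.shape != (nt, self.rank):
            raise ValueError("psi_c shape does not match temporal parameterization")
        # building the bases validates control counts against the grid
        self.spatial_basis()
        if self.temporal_controls is not None:
            self.temporal_basis()

    @property
    def rank(self) -> int:
        return self.phi_c.shape[-1]

    @classmethod
    def zeros(
        cls,
        grid: ImageGrid,
        n_frames: int,
        rank: int,
        spatial_controls: int,
        temporal_controls: Optional[int] = None,
        dtype=np.float64,
    ) -> "LowRankMotionModel":
        nc = spatial_controls
        nt = temporal_controls if temporal_controls is not None else n_frames
        return cls(
            grid=grid,
            n_frames=n_frames,
            phi_c=np.zeros((2, nc, nc, rank), dtype=dtype),
            psi_c=np.zeros((nt, rank), dtype=dtype),
            spatial_controls=spatial_controls,
            temporal_controls=temporal_controls,
        )

    def spatial_basis(self) -> scipy.sparse.csr_matrix:
        """Sparse ``(N, n_ctrl^2)`` tensor-product spatial basis."""
        ny, nx = self.grid.shape
        if nx == ny:
            return _basis_2d(ny, nx, self.spatial_controls)
        by = _basis_1d(ny, self.spatial_controls)
        bx = _basis_1d(nx, self.spatial_controls)
        return scipy.sparse.kron(by, bx, format="csr")

    def temporal_basis(self) -> Optional[scipy.sparse.csr_matrix]:
        if self.temporal_controls is None:
            return None
        return _basis_1d(self.n_frames, self.temporal_controls)

    def psi_dense(self) -> np.ndarray:
        """Per-frame temporal weights, shape ``(M, rank)``."""
        bt = self.temporal_basis()
        psi = self.psi_c if bt is None else bt @ self.psi_c
        return np.asarray(psi)

    def spatial_components(self) -> np.ndarray:
        """Dense spatial components ``(2, N, rank)`` (B-spline expanded Phi)."""
        bs = self.spatial_basis()
        nc2 = self.spatial_controls**2
        return np.stack([bs @ self.phi_c[c].reshape(nc2, self.rank) for c in range(2)])

    def expand(self) -> np.ndarray:
        """Dense displacement fields, shape ``(M, 2, ny, nx)``."""
        u = self.spatial_components()  # (2, N, R)
        psi = self.psi_dense()  # (M, R)
        d = np.einsum("cnr,mr->mcn", u, psi)
        return np.ascontiguousarray(d.reshape(self.n_frames, 2, *self.grid.shape))

    def adjust_reference(self, reference="midposition") -> "LowRankMotionModel":
        """Re-reference the motion fields by temporal-weight subtraction.

        ``"midposition"`` subtracts the temporal mean of the fields; an integer
        subtracts the field of that frame.  Because the fields are
        ``Phi Psi^T`` and the temporal B-spline basis rows sum to one, the
        subtraction is exactly a constant shift of the temporal coefficients,
        so the parameterization is preserved.
        """
        psi_dense = self.psi_dense()
        if reference == "midposition":
            shift = psi_dense.mean(axis=0, keepdims=True)
        else:
            shift = psi_dense[int(reference)][None, :]
        return LowRankMotionModel(
            grid=self.grid,
            n_frames=self.n_frames,
            phi_c=self.phi_c,
            psi_c=self.psi_c - shift,
            spatial_controls=self.spatial_controls,
            temporal_controls=self.temporal_controls,
        )


def expand_motion(model: LowRankMotionModel) -> MotionFieldStack:
    """Expand a low-rank B-spline motion model to dense displacement fields."""
    return MotionFieldStack(model.expand(), grid=model.grid)


# ----------------------------------------------------------------------------
# Warping
# ----------------------------------------------------------------------------

class WarpGeometry:
    """Precomputed sampling positions and Jacobian determinant for fixed D.

    For a fixed displacement stack the warp is linear in the image; this class
    caches the per-frame sample positions ``r + D_t(r)`` and ``det`` weights so
    that repeated applications (FISTA iterations, power method) are cheap.
    """

    def __init__(self, d: np.ndarray, grid: ImageGrid, jacobian_weighting: bool = True):
        d = np.asarray(d)
        if d.ndim == 3:
            d = d[None]
        self.grid = grid
        M = d.shape[0]
        x, y = grid.coordinates()
        rdt = np.float32 if d.dtype == np.float32 else np.float64
        self.px = np.ascontiguousarray(x[None] + d[:, 0], dtype=rdt)
        self.py = np.ascontiguousarray(y[None] + d[:, 1], dtype=rdt)
        if jacobian_weighting:
            self.det = np.ascontiguousarray(jacobian_det(d).astype(rdt))
        else:
            self.det = np.ones((M, *grid.shape), dtype=rdt)
        self.n_frames = M

    def apply(self, q: np.ndarray) -> np.ndarray:
        """Warp a stack ``(M, ny, nx)`` (or an image broadcast over frames)."""
        q = np.asarray(q)
        squeeze = q.ndim == 2
        if squeeze:
            q = np.broadcast_to(q, (self.n_frames, *q.shape))
        coef = prefilter(np.ascontiguousarray(q))
        if not np.iscomplexobj(coef):
            cdt = np.complex64 if coef.dtype == np.float32 else np.complex128
            coef = coef.astype(cdt)
        out = np.empty_like(coef)
        _kernels.gather1(coef, self.px, self.py, out)
        out *= self.det
        return out[0] if squeeze else out

    def adjoint(self, y: np.ndarray) -> np.ndarray:
        """Exact adjoint of :meth:`apply` for complex images."""
        y = np.asarray(y)
        squeeze = y.ndim == 2
        if squeeze:
            y = y[None]
        vals = np.ascontiguousarray(y * self.det)
        out = np.zeros_like(vals)
        _kernels.scatter1(self.px, self.py, vals, out)
        out = prefilter(out)  # the prefilter is self-adjoint
        return out[0] if squeeze else out


def warp_image(q: np.ndarray, d_t: np.ndarray, grid: Optional[ImageGrid] = None) -> np.ndarray:
    """Pull-back warp of one image with determinant weighting.

    ``h(r) = q(r + D(r)) det(grad(r + D))`` with cubic B-spline interpolation and
    zero boundary.  ``d_t`` has shape ``(2, ny, nx)``.
    """
    q = np.asarray(q)
    if grid is None:
        grid = ImageGrid(nx=q.shape[1], ny=q.shape[0], dx=1.0, dy=1.0)
    geom = WarpGeometry(d_t, grid)
    out = geom.apply(q[None])[0]
    if not np.iscomplexobj(q):
        out = out.real.astype(np.result_type(q, np.float64), copy=False)
    return out


def warp_image_adjoint(y: np.ndarray, d_t: np.ndarray, grid: Optional[ImageGrid] = None) -> np.ndarray:
    y = np.asarray(y)
    if grid is None:
        grid = ImageGrid(nx=y.shape[1], ny=y.shape[0], dx=1.0, dy=1.0)
    geom = WarpGeometry(d_t, grid)
    if not np.iscomplexobj(y):
        y = y.astype(np.complex128)
    return geom.adjoint(y[None])[0]


# ----------------------------------------------------------------------------
# Motion-conditional forward model
# ----------------------------------------------------------------------------

class SamplingPlan:
    """Coil-weighted masked Fourier sampling with an exact adjoint.

    Maps image stacks ``(M, ny, nx)`` to per-frame k-space samples.  When every
    frame's mask consists of full k-space lines (rows) with a common count, the
    transform along ky is evaluated only on the sampled rows by small per-frame
    DFT matrix products and the codomain is compact, shape ``(M, nr, C, nx)``;
    otherwise the generic path returns masked full grids ``(M, C, ny, nx)``.
    Both paths compute identical sample values.
    """

    def __init__(self, kspace: DynamicKSpace, coil_maps: CoilMaps, dtype=np.complex128):
        if kspace.kind != "cartesian":
            raise ValueError("sampling plan requires (gridded) Cartesian data")
        self.grid = kspace.grid
        self.n_frames = kspace.n_frames
        self.dtype = np.dtype(dtype)
        self.maps = np.ascontiguousarray(coil_maps.maps.astype(self.dtype))
        self.n_coils = self.maps.shape[0]
        self.masks = kspace.masks
        ny, nx = self.grid.shape
        self.rows = None
        row_like = bool((kspace.masks == kspace.masks[:, :, :1]).all())
        if row_like:
            counts = kspace.masks[:, :, 0].sum(axis=1)
            if (counts == counts[0]).all():
                self.rows = np.stack(
                    [np.flatnonzero(kspace.masks[t, :, 0]) for t in range(self.n_frames)]
                )
        if self.rows is not None:
            f = np.arange(ny)
            w = np.exp(-2j * np.pi * np.outer(f, f) / ny) / np.sqrt(ny)
            self.wdft = np.ascontiguousarray(w.astype(self.dtype))
            self.wdft_h = np.ascontiguousarray(w.conj().T.astype(self.dtype))
            self._cw = np.empty((self.n_frames, ny, self.n_coils * nx), dtype=self.dtype)
            self._ey = np.empty_like(self._cw)

    @property
    def codomain_shape(self):
        ny, nx = self.grid.shape
        if self.rows is not None:
            return (self.n_frames, self.rows.shape[1], self.n_coils, nx)
        return (self.n_frames, self.n_coils, ny, nx)

    def compact_samples(self, samples: np.ndarray) -> np.ndarray:
        """Measured data rearranged into the plan's codomain layout."""
        samples = np.asarray(samples, dtype=self.dtype)
        if self.rows is None:
            return samples * self.masks[:, None, :, :]
        out = np.empty(self.codomain_shape, dtype=self.dtype)
        for t in range(self.n_frames):
            out[t] = samples[t][:, self.rows[t], :].transpose(1, 0, 2)
        return out

    def forward_image(self, w: np.ndarray) -> np.ndarray:
        """Sample a coil-less image stack: coil-weight, FFT, mask/select."""
        w = np.asarray(w, dtype=self.dtype)
        ny, nx = self.grid.shape
        if self.rows is None:
            z = fft2c(self.maps[None, :, :, :] * w[:, None, :, :])
            z *= self.masks[:, None, :, :]
            return z
        cw = self._cw
        for c in range(self.n_coils):
            np.multiply(w, self.maps[c], out=cw[:, :, c * nx : (c + 1) * nx])
        nr = self.rows.shape[1]
        kr = np.empty((self.n_frames, nr, self.n_coils * nx), dtype=self.dtype)
        for t in range(self.n_frames):
            np.matmul(self.wdft[self.rows[t]], cw[t], out=kr[t])
        kr = kr.reshape(self.n_frames, nr, self.n_coils, nx)
        return scipy.fft.fft(kr, axis=-1, norm="ortho", overwrite_x=True)

    def adjoint_k(self, y: np.ndarray) -> np.ndarray:
        """Exact adjoint of :meth:`forward_image`; returns ``(M, ny, nx)``."""
        y = np.asarray(y, dtype=self.dtype)
        ny, nx = self.grid.shape
        if self.rows is None:
            e = ifft2c(y * self.masks[:, None, :, :])
            return np.einsum("cij,mcij->mij", np.conj(self.maps), e)
        nr = self.rows.shape[1]
        yr = scipy.fft.ifft(y, axis=-1, norm="ortho").reshape(
            self.n_frames, nr, self.n_coils * nx
        )
        ey = self._ey
        for t in range(self.n_frames):
            np.matmul(self.wdft_h[:, self.rows[t]], yr[t], out=ey[t])
        img = np.zeros((self.n_frames, ny, nx), dtype=self.dtype)
        for c in range(self.n_coils):
            img += np.conj(self.maps[c]) * ey[:, :, c * nx : (c + 1) * nx]
        return img


class MotionConditionalOperator:
    """``F(. | D)``: warp, coil-weight, FFT and sample a reference series.

    Maps a stack ``Q`` of shape ``(M, ny, nx)`` to per-frame k-space samples
    (see :class:`SamplingPlan` for the codomain layout).  The adjoint is exact
    for fixed ``D``, so the pair can be used in proximal-gradient solvers and
    the power method.
    """

    def __init__(
        self,
        kspace: DynamicKSpace,
        coil_maps: CoilMaps,
        d: Optional[np.ndarray] = None,
        dtype=np.complex128,
        jacobian_weighting: bool = True,
    ):
        self.plan = SamplingPlan(kspace, coil_maps, dtype=dtype)
        self.grid = kspace.grid
        self.n_frames = kspace.n_frames
        self.dtype = np.dtype(dtype)
        self.data = self.plan.compact_samples(kspace.samples)
        self.geometry = None
        if d is not None and np.any(d):
            rdt = np.float32 if self.dtype == np.complex64 else np.float64
            self.geometry = WarpGeometry(
                np.asarray(d, dtype=rdt), self.grid, jacobian_weighting=jacobian_weighting
            )
        self.domain_shape = (self.n_frames, *self.grid.shape)

    def forward(self, q: np.ndarray) -> np.ndarray:
        q = np.asarray(q, dtype=self.dtype)
        w = self.geometry.apply(q) if self.geometry is not None else q
        return self.plan.forward_image(w)

    def adjoint(self, y: np.ndarray) -> np.ndarray:
        img = self.plan.adjoint_k(y)
        if self.geometry is not None:
            img = self.geometry.adjoint(img)
        return img


def forward_signal(
    q_t: np.ndarray,
    d_t: Optional[np.ndarray],
    coil_maps: CoilMaps,
    mask: np.ndarray,
) -> np.ndarray:
    """Per-coil masked k-space of a single frame, shape ``(C, ny, nx)``."""
    w = q_t if d_t is None or not np.any(d_t) else warp_image(
        np.asarray(q_t, dtype=np.complex128), d_t, coil_maps.grid
    )
    z = fft2c(coil_maps.maps * w[None])
    return z * mask[None]


def adjoint_signal(
    samples: np.ndarray,
    d_t: Optional[np.ndarray],
    coil_maps: CoilMaps,
    mask: np.ndarray,
) -> np.ndarray:
    """Exact adjoint of :func:`forward_signal` for fixed ``d_t``."""
    e = ifft2c(samples * mask[None])
    img = np.einsum("cij,cij->ij", np.conj(coil_maps.maps), e)
    if d_t is not None and np.any(d_t):
        img = warp_image_adjoint(img, d_t, coil_maps.grid)
    return img


# ----------------------------------------------------------------------------
# Temporal Fourier transform and spectral norm
# ----------------------------------------------------------------------------

def temporal_fourier(x: np.ndarray, axis: int = 0) -> np.ndarray:
    """Unitary DFT along the frame axis."""
    return scipy.fft.fft(x, axis=axis, norm="ortho")


def temporal_fourier_adjoint(x: np.ndarray, axis: int = 0) -> np.ndarray:
    return scipy.fft.ifft(x, axis=axis, norm="ortho")


def spectral_norm(
    op,
    seed: int = 0,
    tol: float = 1e-4,
    maxiter: int = 100,
    x0: Optional[np.ndarray] = None,
    return_vector: bool = False,
):
    """Largest singular value of a linear operator by the power method.

    Iterates ``x <- F^H F x`` from a seeded random start (or ``x0`` to warm-start
    across alternations) until the eigenvalue estimate of ``F^H F`` changes by
    less than ``tol`` relative; returns its square root, the operator norm.  On
    non-convergence a warning is issued and the best estimate returned.
    """
    import warnings

    if x0 is not None:
        x = np.asarray(x0, dtype=op.dtype).copy()
    else:
        rng = np.random.default_rng(seed)
        x = (
            rng.standard_normal(op.domain_shape) + 1j * rng.standard_normal(op.domain_shape)
        ).astype(op.dtype)
    x /= np.linalg.norm(x.ravel())
    lam_prev = 0.0
    lam = 0.0
    for _ in range(maxiter):
        z = op.adjoint(op.forward(x))
        lam = float(np.real(np.vdot(x.ravel(), z.ravel())))
        nz = np.linalg.norm(z.ravel())
        if nz == 0:
            return (0.0, x) if return_vector else 0.0
        x = z / nz
        if lam_prev > 0 and abs(lam - lam_prev) <= tol * lam:
            break
        lam_prev = lam
    else:
        warnings.warn("power method did not converge; returning best estimate")
    sigma = float(np.sqrt(max(lam, 0.0)))
    return (sigma, x) if return_vector else sigma
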