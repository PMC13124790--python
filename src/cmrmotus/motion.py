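"""Low-rank B-spline motion estimation from k-space (step 2).

For fixed reference images Q, the motion coefficients are estimated by solving

    min_{Phi, Psi}  sum_t || F(D_t | q_t) - s_t ||_2^2  +  lambda_TV ||TV(D)||

with ``D = (B_s Phi)(B_t Psi)^T`` the dense fields expanded from cubic B-spline
control grids, using L-BFGS with an analytic gradient obtained by the exact
chain rule through sampling -> FFT -> coil weighting -> warping -> B-spline
expansion.

The default TV is the standard isotropic total variation applied per
displacement component (forward differences, zero-flux boundary) summed over
components and frames; the literally printed variant
``sqrt(TV_x^2 + TV_y^2)`` is available as ``variant="printed"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.ndimage
import scipy.optimize

from . import _kernels
from .bspline import prefilter
from .config import ReconConfig
from .containers import CoilMaps, DynamicKSpace, MotionFieldStack
from .operators import LowRankMotionModel, SamplingPlan, temporal_fourier

__all__ = [
    "tv_motion",
    "MotionObjective",
    "MotionObjectiveFunction",
    "motion_objective",
    "solve_motion",
    "FrequencySplit",
    "frequency_split",
]

_TV_EPS = 1e-7  # smoothing of the TV gradient only; values are exact


def _fdx(f: np.ndarray) -> np.ndarray:
    d = np.zeros_like(f)
    d[..., :-1] = f[..., 1:] - f[..., :-1]
    return d


def _fdy(f: np.ndarray) -> np.ndarray:
    d = np.zeros_like(f)
    d[..., :-1, :] = f[..., 1:, :] - f[..., :-1, :]
    return d


def _fdx_T(y: np.ndarray) -> np.ndarray:
    x = np.zeros_like(y)
    x[..., 1:] += y[..., :-1]
    x[..., :-1] -= y[..., :-1]
    return x


def _fdy_T(y: np.ndarray) -> np.ndarray:
    x = np.zeros_like(y)
    x[..., 1:, :] += y[..., :-1, :]
    x[..., :-1, :] -= y[..., :-1, :]
    return x


def tv_motion(d, variant: str = "mixed21") -> float:
    """Total variation of a displacement stack.

    ``variant="mixed21"`` (default): per frame and per displacement component,
    the isotropic TV ``sum_i |grad D^c_i|_2``, summed over the two components
    and all frames.  ``variant="printed"`` combines the per-component sums as
    ``sqrt(TV_x^2 + TV_y^2)`` per frame.
    """
    if isinstance(d, MotionFieldStack):
        d = d.d
    d = np.asarray(d, dtype=np.float64)
    if d.ndim == 3:
        d = d[None]
    per_comp = np.sqrt(_fdx(d) ** 2 + _fdy(d) ** 2).sum(axis=(2, 3))  # (M, 2)
    if variant == "mixed21":
        return float(per_comp.sum())
    if variant == "printed":
        return float(np.sqrt((per_comp**2).sum(axis=1)).sum())
    raise ValueError(f"unknown TV variant {variant!r}")


def _tv_value_grad(d: np.ndarray, variant: str):
    """Exact TV value and (smoothed) gradient w.r.t. the dense fields."""
    fx = _fdx(d)
    fy = _fdy(d)
    mag = np.sqrt(fx**2 + fy**2)
    per_comp = mag.sum(axis=(2, 3))  # (M, 2)
    smooth = np.sqrt(fx**2 + fy**2 + _TV_EPS**2)
    gx = fx / smooth
    gy = fy / smooth
    if variant == "mixed21":
        value = float(per_comp.sum())
        grad = _fdx_T(gx) + _fdy_T(gy)
    elif variant == "printed":
        frame_val = np.sqrt((per_comp**2).sum(axis=1))  # (M,)
        value = float(frame_val.sum())
        w = per_comp / np.maximum(frame_val, _TV_EPS)[:, None]  # (M, 2)
        grad = _fdx_T(gx * w[:, :, None, None]) + _fdy_T(gy * w[:, :, None, None])
    else:
        raise ValueError(f"unknown TV variant {variant!r}")
    return value, grad


@dataclass
class MotionObjective:
    """Value and gradient of the motion inverse problem at one point."""

    data_term: float
    tv_term: float
    lambda_tv: float
    grad_phi: np.ndarray
    grad_psi: np.ndarray

    @property
    def total(self) -> float:
        return self.data_term + self.lambda_tv * self.tv_term


class MotionObjectiveFunction:
    """Callable objective/gradient for L-BFGS over ``(Phi_c, Psi_c)``.

    Precomputes the B-spline coefficients of the fixed reference series Q and
    the sparse spatial/temporal bases, so each evaluation costs one warp-gather,
    one batched coil FFT round trip and two thin GEMM projections.
    """

    def __init__(
        self,
        q: np.ndarray,
        kspace: DynamicKSpace,
        coil_maps: CoilMaps,
        template: LowRankMotionModel,
        lambda_tv: float,
        tv_variant: str = "mixed21",
        dtype=np.complex128,
        jacobian_weighting: bool = True,
    ):
        if kspace.kind != "cartesian":
            raise ValueError("motion estimation operates on (gridded) Cartesian data")
        self.grid = kspace.grid
        self.M = kspace.n_frames
        self.dtype = np.dtype(dtype)
        self.rdt = np.float32 if self.dtype == np.complex64 else np.float64
        self.coef = prefilter(np.ascontiguousarray(q.astype(self.dtype)))
        self.plan = SamplingPlan(kspace, coil_maps, dtype=self.dtype)
        self.s = self.plan.compact_samples(kspace.samples)
        self.template = template
        self.lambda_tv = float(lambda_tv)
        self.tv_variant = tv_variant
        self.jacobian_weighting = jacobian_weighting
        self.bs = template.spatial_basis().astype(self.rdt)
        bt = template.temporal_basis()
        self.bt = None if bt is None else bt.astype(self.rdt)
        x, y = self.grid.coordinates()
        self.xg = x.astype(self.rdt)
        self.yg = y.astype(self.rdt)
        self._phi_shape = template.phi_c.shape
        self._psi_shape = template.psi_c.shape
        self.n_eval = 0

    # -- parameter packing -------------------------------------------------
    def pack(self, phi_c: np.ndarray, psi_c: np.ndarray) -> np.ndarray:
        return np.concatenate([phi_c.ravel(), psi_c.ravel()]).astype(np.float64)

    def unpack(self, x: np.ndarray):
        n_phi = int(np.prod(self._phi_shape))
        phi = x[:n_phi].reshape(self._phi_shape).astype(self.rdt)
        psi = x[n_phi:].reshape(self._psi_shape).astype(self.rdt)
        return phi, psi

    def make_model(self, x: np.ndarray) -> LowRankMotionModel:
        phi, psi = self.unpack(x)
        t = self.template
        return LowRankMotionModel(
            grid=t.grid,
            n_frames=t.n_frames,
            phi_c=phi.astype(np.float64),
            psi_c=psi.astype(np.float64),
            spatial_controls=t.spatial_controls,
            temporal_controls=t.temporal_controls,
        )

    # -- evaluation --------------------------------------------------------
    def value_and_grad(self, phi_c: np.ndarray, psi_c: np.ndarray) -> MotionObjective:
        self.n_eval += 1
        M = self.M
        ny, nx = self.grid.shape
        N = ny * nx
        rank = phi_c.shape[-1]
        nc2 = phi_c.shape[1] * phi_c.shape[2]

        psi = psi_c if self.bt is None else self.bt @ psi_c  # (M, R)
        u = np.stack([self.bs @ phi_c[c].reshape(nc2, rank) for c in range(2)])  # (2,N,R)
        d = np.einsum("cnr,mr->mcn", u, psi).reshape(M, 2, ny, nx)
        d = np.ascontiguousarray(d, dtype=self.rdt)

        px = np.empty((M, ny, nx), dtype=self.rdt)
        py = np.empty_like(px)
        det = np.empty_like(px)
        _kernels.warp_prep(d, self.xg, self.yg, px, py, det)

        w0 = np.empty((M, ny, nx), dtype=self.dtype)
        gx = np.empty_like(w0)
        gy = np.empty_like(w0)
        _kernels.gather3(self.coef, px, py, w0, gx, gy)
        w = w0 * det if self.jacobian_weighting else w0

        z = self.plan.forward_image(w)
        z -= self.s
        f_data = float(np.real(np.vdot(z, z)))
        e = self.plan.adjoint_k(z)

        # chain rule back to the dense fields (exact stencil transposes)
        g_d = np.empty_like(d)
        if self.jacobian_weighting:
            _kernels.det_chain(e, gx, gy, w0, d, det, g_d)
        else:
            g_d[:, 0] = 2.0 * (np.real(e) * np.real(gx) + np.imag(e) * np.imag(gx))
            g_d[:, 1] = 2.0 * (np.real(e) * np.real(gy) + np.imag(e) * np.imag(gy))

        tv_val = 0.0
        if self.lambda_tv > 0:
            if self.tv_variant == "mixed21":
                tv_val = _kernels.tv_mixed21_grad(d, _TV_EPS, self.lambda_tv, g_d)
            else:
                tv_val, tv_grad = _tv_value_grad(d.astype(np.float64), self.tv_variant)
                g_d += (self.lambda_tv * tv_grad).astype(self.rdt)

        g_flat = g_d.reshape(M, 2, N)
        grad_phi = np.empty_like(phi_c)
        grad_psi_dense = np.zeros((M, rank), dtype=self.rdt)
        for c in range(2):
            gu = np.einsum("mn,mr->nr", g_flat[:, c, :], psi)  # (N, R)
            grad_phi[c] = (self.bs.T @ gu).reshape(phi_c.shape[1:])
            grad_psi_dense += np.einsum("mn,nr->mr", g_flat[:, c, :], u[c])
        grad_psi = grad_psi_dense if self.bt is None else self.bt.T @ grad_psi_dense

        return MotionObjective(
            data_term=f_data,
            tv_term=tv_val,
            lambda_tv=self.lambda_tv,
            grad_phi=grad_phi.astype(np.float64),
            grad_psi=np.asarray(grad_psi, dtype=np.float64),
        )

    def __call__(self, x: np.ndarray):
        phi, psi = self.unpack(np.asarray(x, dtype=np.float64))
        obj = self.value_and_grad(phi, psi)
        return obj.total, self.pack(obj.grad_phi, obj.grad_psi)


def motion_objective(
    model: LowRankMotionModel,
    q: np.ndarray,
    kspace: DynamicKSpace,
    coil_maps: CoilMaps,
    lambda_tv: float,
    tv_variant: str = "mixed21",
    dtype=np.complex128,
) -> MotionObjective:
    """Evaluate the motion objective and its analytic gradient at ``model``."""
    fn = MotionObjectiveFunction(
        q, kspace, coil_maps, model, lambda_tv, tv_variant=tv_variant, dtype=dtype
    )
    return fn.value_and_grad(
        model.phi_c.astype(fn.rdt), model.psi_c.astype(fn.rdt)
    )


def solve_motion(
    q: np.ndarray,
    kspace: DynamicKSpace,
    coil_maps: CoilMaps,
    config: ReconConfig,
    seed: Optional[int] = None,
    init_model: Optional[LowRankMotionModel] = None,
) -> LowRankMotionModel:
    """Estimate the low-rank B-spline motion model for fixed reference images.

    Without ``init_model``, Phi and Psi start from uniform(-1, 1) random
    coefficients, band-limited on the spatial control grid and rescaled so the
    largest initial displacement is ``config.motion_init_scale`` voxels
    (sub-voxel), then refined by L-BFGS (memory ``config.lbfgs_memory``, at
    most ``config.max_iter_motion`` iterations).  During alternating
    reconstruction, later rounds pass the previous round's model as
    ``init_model``: the image/motion factorization has a gauge freedom, and a
    fresh random start each round lets the fields drift to a different gauge
    even when the data fit is unchanged; warm-starting anchors them.
    Deterministic given the seed.  The fitted model carries a ``fit_info``
    dict (objective, iteration and evaluation counts, convergence status).
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    template = LowRankMotionModel.zeros(
        kspace.grid,
        kspace.n_frames,
        config.rank_d,
        config.spatial_controls,
        config.temporal_controls,
    )
    if init_model is not None:
        if (
            init_model.phi_c.shape != template.phi_c.shape
            or init_model.psi_c.shape != template.psi_c.shape
        ):
            raise ValueError("init_model does not match the configured motion model")
        phi0 = init_model.phi_c.copy()
        psi0 = init_model.psi_c.copy()
    else:
        phi0 = rng.uniform(-1.0, 1.0, size=template.phi_c.shape)
        psi0 = rng.uniform(-1.0, 1.0, size=template.psi_c.shape)
        # band-limit the spatial coefficients: raw white-noise control grids
        # give displacement fields with O(1) gradients that survive in
        # signal-free regions (no data gradient there) and inflate the warp
        # operator norm
        if config.spatial_controls >= 8:
            sigma = config.spatial_controls / 16.0
            phi0 = scipy.ndimage.gaussian_filter(phi0, sigma=(0, sigma, sigma, 0))
        probe = LowRankMotionModel(
            grid=template.grid,
            n_frames=template.n_frames,
            phi_c=phi0,
            psi_c=psi0,
            spatial_controls=template.spatial_controls,
            temporal_controls=template.temporal_controls,
        )
        dmax = float(np.abs(probe.expand()).max())
        if dmax > 0:
            phi0 = phi0 * (config.motion_init_scale / dmax)

    fn = MotionObjectiveFunction(
        q,
        kspace,
        coil_maps,
        template,
        config.lambda_tv,  # rescaled below once the sampling plan exists
        dtype=config.dtype,
        jacobian_weighting=config.jacobian_weighting,
    )
    from .lps import resolve_lambda_unit

    # the TV weight converts voxels to the squared-intensity units of the data
    # term; the same lambda_unit calibration applies, squared
    fn.lambda_tv = config.lambda_tv * resolve_lambda_unit(config, fn.plan, fn.s) ** 2
    x0 = fn.pack(phi0, psi0)
    res = scipy.optimize.minimize(
        fn,
        x0,
        jac=True,
        method="L-BFGS-B",
        options=dict(
            maxcor=config.lbfgs_memory,
            maxiter=config.max_iter_motion,
            ftol=config.motion_ftol,
            gtol=1e-12,
        ),
    )
    if res.status not in (0, 1):  # 1 = iteration cap reached
        warnings.warn(f"L-BFGS terminated early ({res.message}); returning best iterate")
    model = fn.make_model(res.x)
    model.fit_info = dict(
        objective=float(res.fun),
        iterations=int(res.nit),
        n_evaluations=int(res.nfev),
        status=int(res.status),
        message=str(res.message),
        seed=int(seed),
    )
    return model


# ----------------------------------------------------------------------------
# Frequency-based disentanglement of motion components
# ----------------------------------------------------------------------------

@dataclass
class FrequencySplit:
    """Partition of motion components into low/high temporal-frequency groups."""

    low: list
    high: list
    dominant_freq_hz: np.ndarray
    low_fields: MotionFieldStack
    high_fields: MotionFieldStack
    model: LowRankMotionModel


def _band_unmix(psi: np.ndarray, low_bins: np.ndarray):
    """Rotation maximizing per-component band purity.

    The factorization ``D = Phi Psi^T`` is invariant under any invertible R x R
    mixing, so classifying raw Psi columns is ill-posed.  The generalized
    eigenvectors of (low-band energy, total energy) give the unmixing directions
    with extremal low-band energy fractions.
    """
    import scipy.linalg

    f = temporal_fourier(psi, axis=0)
    fl = f[low_bins]
    m_low = np.real(fl.conj().T @ fl)
    m_tot = np.real(f.conj().T @ f)
    ridge = 1e-12 * max(np.trace(m_tot), 1.0)
    m_tot = m_tot + ridge * np.eye(psi.shape[1])
    _, v = scipy.linalg.eigh(0.5 * (m_low + m_low.T), 0.5 * (m_tot + m_tot.T))
    return v  # columns ordered by increasing low-band fraction


def frequency_split(
    model: LowRankMotionModel,
    cutoff_hz: float,
    frame_interval_s: float,
    unmix: bool = True,
) -> FrequencySplit:
    """Separate motion components by the frequency content of Psi.

    Each rank component is classified by the dominant temporal frequency of its
    temporal weight vector: below ``cutoff_hz`` is "low" (e.g. respiration /
    static), at or above is "high" (e.g. cardiac).  With ``unmix=True``
    (default) the components are first rotated to extremal band purity, which
    removes the arbitrary mixing freedom of the low-rank factorization; the
    classification is invariant to component sign flips either way.
    """
    dt = float(frame_interval_s)
    nyquist = 0.5 / dt
    if not 0.0 < cutoff_hz < nyquist:
        raise ValueError(f"cutoff must lie in (0, {nyquist}) Hz")
    psi = model.psi_dense().astype(np.float64)
    M, rank = psi.shape
    freqs = np.fft.fftfreq(M, d=dt)
    low_bins = np.abs(freqs) < cutoff_hz

    phi_dense = model.phi_c.astype(np.float64)
    if unmix and rank > 1:
        v = _band_unmix(psi, low_bins)
        psi = psi @ v
        vinv_t = np.linalg.inv(v).T
        phi_dense = np.tensordot(phi_dense, vinv_t, axes=([3], [0]))

    spec = np.abs(temporal_fourier(psi, axis=0)) ** 2
    half = slice(0, M // 2 + 1)  # nonnegative frequencies
    dominant = np.array([abs(freqs[half][int(np.argmax(spec[half, r]))]) for r in range(rank)])
    low = [r for r in range(rank) if dominant[r] < cutoff_hz]
    high = [r for r in range(rank) if dominant[r] >= cutoff_hz]

    unmixed = LowRankMotionModel(
        grid=model.grid,
        n_frames=model.n_frames,
        phi_c=phi_dense,
        psi_c=psi if model.temporal_controls is None else psi,
        spatial_controls=model.spatial_controls,
        temporal_controls=None,
    )

    def group_fields(idx):
        d = np.zeros((model.n_frames, 2, *model.grid.shape))
        if idx:
            sub = LowRankMotionModel(
                grid=model.grid,
                n_frames=model.n_frames,
                phi_c=np.ascontiguousarray(phi_dense[..., idx]),
                psi_c=np.ascontiguousarray(psi[:, idx]),
                spatial_controls=model.spatial_controls,
                temporal_controls=None,
            )
            d = sub.expand()
        return MotionFieldStack(d, grid=model.grid)

    return FrequencySplit(
        low=low,
        high=high,
        dominant_freq_hz=dominant,
        low_fields=group_fields(low),
        high_fields=group_fields(high),
        model=unmixed,
    )
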