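"""Operator correctness: B-spline expansion, warping, forward/adjoint pairs,
temporal Fourier and spectral norm."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cmrmotus.bspline import bspline_basis_matrix, bspline_kernel, prefilter
from cmrmotus.containers import DynamicKSpace, ImageGrid
from cmrmotus.operators import (
    LowRankMotionModel,
    MotionConditionalOperator,
    adjoint_signal,
    expand_motion,
    fft2c,
    forward_signal,
    grad_x,
    grad_x_T,
    grad_y,
    grad_y_T,
    spectral_norm,
    temporal_fourier,
    temporal_fourier_adjoint,
    warp_image,
    warp_image_adjoint,
)
from cmrmotus.phantom import make_coil_maps


class TestBsplineBasis:
    def test_partition_of_unity_and_interpolation(self):
        b = bspline_basis_matrix(25, 9)
        np.testing.assert_allclose(np.asarray(b.sum(axis=1)).ravel(), 1.0, atol=1e-12)

    def test_control_count_bounds(self):
        with pytest.raises(ValueError):
            bspline_basis_matrix(10, 3)
        with pytest.raises(ValueError):
            bspline_basis_matrix(10, 11)

    def test_prefilter_inverts_kernel_at_nodes(self, rng):
        # gather at integer positions must reproduce the image exactly
        q = rng.standard_normal((2, 12, 14)) + 1j * rng.standard_normal((2, 12, 14))
        c = prefilter(np.ascontiguousarray(q))
        # convolve coefficients with the B3 kernel at integer offsets
        k = bspline_kernel(np.array([-1.0, 0.0, 1.0]))
        rec = np.zeros_like(q)
        for o, w in zip((-1, 0, 1), k):
            shifted = np.zeros_like(c)
            if o == 0:
                shifted = c.copy()
            elif o == 1:
                shifted[:, :, 1:] = c[:, :, :-1]
            else:
                shifted[:, :, :-1] = c[:, :, 1:]
            rec += w * shifted
        c2 = rec
        rec = np.zeros_like(c2)
        for o, w in zip((-1, 0, 1), k):
            shifted = np.zeros_like(c2)
            if o == 0:
                shifted = c2.copy()
            elif o == 1:
                shifted[:, 1:, :] = c2[:, :-1, :]
            else:
                shifted[:, :-1, :] = c2[:, 1:, :]
            rec += w * shifted
        np.testing.assert_allclose(rec, q, atol=1e-10)


class TestExpandMotion:
    def test_zero_coefficients_give_zero_fields(self, grid16):
        model = LowRankMotionModel.zeros(grid16, 5, 2, 6)
        assert np.all(expand_motion(model).d == 0)

    def test_constant_translation(self, grid16):
        model = LowRankMotionModel.zeros(grid16, 4, 1, 6)
        model.phi_c[0, :, :, 0] = 2.0  # constant x-translation via partition of unity
        model.psi_c[:, 0] = 1.0
        d = model.expand()
        np.testing.assert_allclose(d[:, 0], 2.0, atol=1e-12)
        np.testing.assert_allclose(d[:, 1], 0.0, atol=1e-12)

    def test_matches_dense_tensor_product_sum(self, grid16, rng):
        model = LowRankMotionModel.zeros(grid16, 8, 2, 6)
        model.phi_c = rng.standard_normal(model.phi_c.shape)
        model.psi_c = rng.standard_normal(model.psi_c.shape)
        d = model.expand()
        b1 = bspline_basis_matrix(16, 6).toarray()
        for (t, c, i, j) in [(3, 1, 5, 7), (0, 0, 0, 0), (7, 1, 15, 2)]:
            val = sum(
                b1[i, p] * b1[j, q] * model.phi_c[c, p, q, r] * model.psi_c[t, r]
                for p in range(6)
                for q in range(6)
                for r in range(2)
            )
            assert d[t, c, i, j] == pytest.approx(val, abs=1e-10)

    def test_linear_in_phi_and_psi(self, grid16, rng):
        m = LowRankMotionModel.zeros(grid16, 4, 1, 6)
        m.phi_c = rng.standard_normal(m.phi_c.shape)
        m.psi_c = rng.standard_normal(m.psi_c.shape)
        d = m.expand()
        m2 = LowRankMotionModel(
            grid=m.grid, n_frames=4, phi_c=3.0 * m.phi_c, psi_c=m.psi_c,
            spatial_controls=6,
        )
        np.testing.assert_allclose(m2.expand(), 3.0 * d, atol=1e-12)
        m3 = LowRankMotionModel(
            grid=m.grid, n_frames=4, phi_c=m.phi_c, psi_c=-2.0 * m.psi_c,
            spatial_controls=6,
        )
        np.testing.assert_allclose(m3.expand(), -2.0 * d, atol=1e-12)


class TestWarp:
    def test_identity_at_zero_displacement(self, rng):
        q = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
        np.testing.assert_allclose(warp_image(q, np.zeros((2, 16, 16))), q, atol=1e-13)

    def test_rigid_translation_preserves_interior_mass(self, grid32):
        x, y = grid32.coordinates()
        blob = np.exp(-((x - 16) ** 2 + (y - 16) ** 2) / (2 * 3.0**2))
        d = np.zeros((2, 32, 32))
        d[0] = 2.0
        d[1] = -1.0
        h = warp_image(blob, d)
        assert h.sum() == pytest.approx(blob.sum(), rel=1e-5)
        # shifted blob peak moved opposite to the pull-back displacement
        iy, ix = np.unravel_index(np.argmax(h), h.shape)
        assert (ix, iy) == (14, 17)

    def test_uniform_dilation_det_weighting_conserves_mass(self, grid32):
        a = 0.1
        x, y = grid32.coordinates()
        blob = np.exp(-((x - 15.5) ** 2 + (y - 15.5) ** 2) / (2 * 2.5**2))
        d = np.stack([a * (x - 15.5), a * (y - 15.5)])
        h = warp_image(blob, d)
        # det of r -> r + a(r - c) is (1 + a)^2; the pull-back then conserves mass
        from cmrmotus.operators import jacobian_det

        np.testing.assert_allclose(jacobian_det(d), (1 + a) ** 2, atol=1e-10)
        assert h.sum() == pytest.approx(blob.sum(), rel=0.01)

    def test_adjoint_dot_products(self, grid16, rng):
        for _ in range(20):
            d = 0.8 * rng.standard_normal((2, 16, 16))
            x = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
            y = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
            lhs = np.vdot(y, warp_image(x, d))
            rhs = np.vdot(warp_image_adjoint(y, d), x)
            assert abs(lhs - rhs) / (np.linalg.norm(x) * np.linalg.norm(y)) < 1e-6


class TestFiniteDifferenceTransposes:
    def test_grad_transposes_are_exact(self, rng):
        x = rng.standard_normal((3, 10, 12))
        y = rng.standard_normal((3, 10, 12))
        assert np.vdot(y, grad_x(x)) == pytest.approx(np.vdot(grad_x_T(y), x))
        assert np.vdot(y, grad_y(x)) == pytest.approx(np.vdot(grad_y_T(y), x))


class TestForwardSignal:
    def test_reduces_to_fft_for_uniform_single_coil(self, grid16, rng):
        maps = make_coil_maps(grid16, 1)
        q = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
        mask = np.ones((16, 16), dtype=bool)
        s = forward_signal(q, None, maps, mask)
        np.testing.assert_allclose(s[0], fft2c(q), atol=1e-12)

    def test_global_translation_matches_fourier_shift_theorem(self, grid32):
        x, y = grid32.coordinates()
        img = np.exp(-((x - 15.5) ** 2 + (y - 15.5) ** 2) / (2 * 4.0**2))
        maps = make_coil_maps(grid32, 1)
        mask = np.ones((32, 32), dtype=bool)
        tau = (1.3, -0.7)
        d = np.stack([np.full((32, 32), -tau[0]), np.full((32, 32), -tau[1])])
        s = forward_signal(img.astype(complex), d, maps, mask)[0]
        kx = np.fft.fftfreq(32)[None, :]
        ky = np.fft.fftfreq(32)[:, None]
        ref = fft2c(img) * np.exp(-2j * np.pi * (kx * tau[0] + ky * tau[1]))
        assert np.linalg.norm(s - ref) / np.linalg.norm(ref) < 1e-3

    def test_per_frame_adjoint_dot_product(self, grid16, rng):
        maps = make_coil_maps(grid16, 3)
        mask = np.zeros((16, 16), dtype=bool)
        mask[rng.choice(16, 5, replace=False)] = True
        for _ in range(5):
            d = 0.5 * rng.standard_normal((2, 16, 16))
            x = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
            y = (rng.standard_normal((3, 16, 16)) + 1j * rng.standard_normal((3, 16, 16))) * mask
            lhs = np.vdot(y, forward_signal(x, d, maps, mask))
            rhs = np.vdot(adjoint_signal(y, d, maps, mask), x)
            assert abs(lhs - rhs) / (np.linalg.norm(x) * np.linalg.norm(y)) < 1e-6

    def test_adjoint_linearity(self, grid16, rng):
        maps = make_coil_maps(grid16, 2)
        mask = np.ones((16, 16), dtype=bool)
        d = 0.5 * rng.standard_normal((2, 16, 16))
        y1 = rng.standard_normal((2, 16, 16)) + 1j * rng.standard_normal((2, 16, 16))
        y2 = rng.standard_normal((2, 16, 16)) + 1j * rng.standard_normal((2, 16, 16))
        a = 2.0 - 1.5j
        lhs = adjoint_signal(a * y1 + y2, d, maps, mask)
        rhs = a * adjoint_signal(y1, d, maps, mask) + adjoint_signal(y2, d, maps, mask)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)


class TestStackOperator:
    def test_stack_adjoint_dot_products(self, random_kspace_16, rng):
        kspace, maps = random_kspace_16
        d = 0.6 * rng.standard_normal((kspace.n_frames, 2, 16, 16))
        for dd in (None, d):
            op = MotionConditionalOperator(kspace, maps, dd)
            for _ in range(10):
                x = rng.standard_normal(op.domain_shape) + 1j * rng.standard_normal(op.domain_shape)
                y = rng.standard_normal(op.data.shape) + 1j * rng.standard_normal(op.data.shape)
                lhs = np.vdot(y, op.forward(x))
                rhs = np.vdot(op.adjoint(y), x)
                assert abs(lhs - rhs) / (np.linalg.norm(x) * np.linalg.norm(y)) < 1e-6

    def test_row_fast_path_matches_samples(self, small_study):
        # forward of the truth frames reproduces the measured noisy data closely
        kspace, maps, truth = small_study
        op = MotionConditionalOperator(kspace, maps, None)
        pred = op.forward(truth.frames.astype(complex))
        resid = pred - op.data
        snr = np.linalg.norm(op.data) / np.linalg.norm(resid)
        assert snr > 10  # only the 30 dB simulation noise remains


class TestTemporalFourier:
    @given(st.integers(min_value=1, max_value=9))
    @settings(max_examples=8, deadline=None)
    def test_unitarity_and_parseval(self, m):
        rng = np.random.default_rng(m)
        x = rng.standard_normal((m, 4, 4)) + 1j * rng.standard_normal((m, 4, 4))
        np.testing.assert_allclose(temporal_fourier_adjoint(temporal_fourier(x)), x, atol=1e-12)
        assert np.linalg.norm(temporal_fourier(x)) == pytest.approx(np.linalg.norm(x))

    def test_static_series_concentrates_in_dc(self):
        x = np.ones((8, 3, 3), dtype=complex)
        z = temporal_fourier(x)
        assert np.abs(z[0]).min() > 0
        np.testing.assert_allclose(z[1:], 0, atol=1e-12)


class _DenseOp:
    def __init__(self, mat):
        self.mat = mat
        self.domain_shape = (mat.shape[1],)
        self.dtype = np.complex128

    def forward(self, x):
        return self.mat @ x

    def adjoint(self, y):
        return self.mat.conj().T @ y


class TestSpectralNorm:
    def test_identity_and_diagonal(self):
        assert spectral_norm(_DenseOp(np.eye(8)), seed=0) == pytest.approx(1.0, rel=1e-3)
        assert spectral_norm(_DenseOp(np.diag([4.0, 1.0])), seed=0) == pytest.approx(4.0, rel=1e-3)

    def test_matches_dense_svd(self, rng):
        mat = rng.standard_normal((32, 32)) + 1j * rng.standard_normal((32, 32))
        sigma = spectral_norm(_DenseOp(mat), seed=1, tol=1e-8, maxiter=2000)
        assert sigma == pytest.approx(np.linalg.svd(mat, compute_uv=False)[0], rel=1e-3)


class TestScatteredMaskFallback:
    def test_gridded_radial_operator_adjoint(self, grid16, rng):
        # scattered (non-row) masks take the generic full-grid path
        from cmrmotus.phantom import PhantomConfig, make_coil_maps, simulate_kspace, generate_phantom

        cfg = PhantomConfig(
            n_frames=3, nx=16, ny=16, n_coils=2,
            sampling_scheme="radial_golden_angle", readouts_per_frame=4,
            noise_sigma=0.0, seed=5,
        )
        truth = generate_phantom(cfg)
        maps = make_coil_maps(grid16, 2)
        ks = simulate_kspace(truth, maps, cfg).gridded()
        op = MotionConditionalOperator(ks, maps, 0.4 * rng.standard_normal((3, 2, 16, 16)))
        assert op.plan.rows is None  # fallback path engaged
        for _ in range(5):
            x = rng.standard_normal(op.domain_shape) + 1j * rng.standard_normal(op.domain_shape)
            y = rng.standard_normal(op.data.shape) + 1j * rng.standard_normal(op.data.shape)
            lhs = np.vdot(y, op.forward(x))
            rhs = np.vdot(op.adjoint(y), x)
            assert abs(lhs - rhs) / (np.linalg.norm(x) * np.linalg.norm(y)) < 1e-6
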