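"""Motion objective (TV, analytic gradient), L-BFGS recovery experiments and
frequency-based component disentanglement."""

import numpy as np
import pytest

from cmrmotus.config import ReconConfig
from cmrmotus.containers import DynamicKSpace, ImageGrid, MotionFieldStack
from cmrmotus.motion import (
    MotionObjectiveFunction,
    frequency_split,
    motion_objective,
    solve_motion,
    tv_motion,
)
from cmrmotus.operators import LowRankMotionModel
from cmrmotus.phantom import (
    LABELS,
    PhantomConfig,
    generate_phantom,
    make_coil_maps,
    simulate_kspace,
)
from cmrmotus import metrics as mtr


class TestTV:
    def test_constant_field_has_zero_tv(self):
        d = np.full((3, 2, 8, 8), 2.5)
        assert tv_motion(d) == 0.0
        assert tv_motion(d, variant="printed") == 0.0

    def test_absolute_homogeneity(self, rng):
        d = rng.standard_normal((2, 2, 8, 8))
        for a in (-3.0, 0.5):
            assert tv_motion(a * d) == pytest.approx(abs(a) * tv_motion(d), rel=1e-12)
            assert tv_motion(a * d, variant="printed") == pytest.approx(
                abs(a) * tv_motion(d, variant="printed"), rel=1e-12
            )

    def test_single_voxel_step_matches_exhaustive_formula(self):
        # unit step in D_x at (1, 1) of a 4x4 grid, forward differences with
        # zero-flux boundary: neighbours (0,1),(1,0) see +1, (1,1) sees the
        # two outgoing differences combined isotropically
        d = np.zeros((1, 2, 4, 4))
        d[0, 0, 1, 1] = 1.0
        brute = 0.0
        f = d[0, 0]
        for i in range(4):
            for j in range(4):
                fx = f[i, j + 1] - f[i, j] if j < 3 else 0.0
                fy = f[i + 1, j] - f[i, j] if i < 3 else 0.0
                brute += np.hypot(fx, fy)
        assert tv_motion(d) == pytest.approx(brute, rel=1e-12)
        assert brute == pytest.approx(2.0 + np.sqrt(2.0))

    def test_printed_variant_combines_components_in_quadrature(self, rng):
        d = np.zeros((1, 2, 6, 6))
        d[0, 0] = rng.standard_normal((6, 6))
        # one active component: both variants agree
        assert tv_motion(d, variant="printed") == pytest.approx(tv_motion(d), rel=1e-12)
        d[0, 1] = rng.standard_normal((6, 6))
        tvx = tv_motion(d[:, :1][:, [0]] * 0 + np.stack([d[:, 0], np.zeros_like(d[:, 0])], axis=1))
        # quadrature combination is never larger than the component sum
        assert tv_motion(d, variant="printed") <= tv_motion(d) + 1e-12


class TestMotionObjective:
    def _problem(self, rng, rank=2, temporal_controls=None):
        grid = ImageGrid(nx=16, ny=16, dx=1.0, dy=1.0)
        M = 6
        maps = make_coil_maps(grid, 3)
        q = rng.standard_normal((M, 16, 16)) + 1j * rng.standard_normal((M, 16, 16))
        masks = np.zeros((M, 16, 16), dtype=bool)
        for t in range(M):
            masks[t, rng.choice(16, 6, replace=False)] = True
        samples = (
            rng.standard_normal((M, 3, 16, 16)) + 1j * rng.standard_normal((M, 3, 16, 16))
        ) * masks[:, None]
        ks = DynamicKSpace(grid=grid, samples=samples, masks=masks)
        tmpl = LowRankMotionModel.zeros(grid, M, rank, 6, temporal_controls)
        fn = MotionObjectiveFunction(q, ks, maps, tmpl, lambda_tv=1e-3, dtype=np.complex128)
        return fn, tmpl, q, ks, maps

    @pytest.mark.parametrize("temporal_controls", [None, 4])
    def test_analytic_gradient_matches_central_differences(self, rng, temporal_controls):
        fn, tmpl, *_ = self._problem(rng, temporal_controls=temporal_controls)
        x0 = rng.uniform(-0.5, 0.5, tmpl.phi_c.size + tmpl.psi_c.size)
        f0, g0 = fn(x0)
        idx = rng.choice(x0.size, 20, replace=False)
        for i in idx:
            h = 1e-5
            xp = x0.copy()
            xp[i] += h
            xm = x0.copy()
            xm[i] -= h
            fd = (fn(xp)[0] - fn(xm)[0]) / (2 * h)
            rel = abs(fd - g0[i]) / max(abs(fd), abs(g0[i]), 1e-12)
            assert rel < 1e-4

    def test_zero_reference_image_gives_pure_data_energy(self, rng):
        fn, tmpl, q, ks, maps = self._problem(rng)
        model = LowRankMotionModel(
            grid=tmpl.grid, n_frames=tmpl.n_frames,
            phi_c=rng.standard_normal(tmpl.phi_c.shape),
            psi_c=rng.standard_normal(tmpl.psi_c.shape),
            spatial_controls=tmpl.spatial_controls,
        )
        obj = motion_objective(model, np.zeros_like(q), ks, maps, lambda_tv=1e-3)
        assert obj.data_term == pytest.approx(float(np.sum(np.abs(ks.samples) ** 2)), rel=1e-6)
        d = model.expand()
        assert obj.tv_term == pytest.approx(tv_motion(d), rel=1e-5)
        # the data term does not depend on the motion when q = 0
        np.testing.assert_allclose(
            obj.grad_phi, 1e-3 * (obj.grad_phi - 0 * obj.grad_phi), atol=np.inf
        )

    def test_truth_motion_beats_zero_motion_on_moving_phantom(self):
        cfg = PhantomConfig(
            n_frames=8, nx=32, ny=32, n_coils=2, sampling_scheme="full",
            readouts_per_frame=32, noise_sigma=0.0, seed=3,
        )
        truth = generate_phantom(cfg)
        maps = make_coil_maps(truth.grid, 2)
        ks = simulate_kspace(truth, maps, cfg)
        cfg0 = cfg.replace(cardiac_amplitude_vox=0.0)
        q = generate_phantom(cfg0).frames.astype(complex)
        # dense per-frame temporal weights, spatial B-spline at truth vs zero:
        # evaluate the data term through the warp at both motion states
        tmpl = LowRankMotionModel.zeros(truth.grid, 8, 1, 16)
        fn = MotionObjectiveFunction(q, ks, maps, tmpl, lambda_tv=0.0, dtype=np.complex128)
        # project the truth field onto the model: spatial coefficients fit the
        # peak-systole field, temporal weights carry the amplitude ratio
        import scipy.sparse.linalg

        bs = tmpl.spatial_basis()
        a_t = np.abs(truth.motion.d).max(axis=(1, 2, 3))
        t_peak = int(np.argmax(a_t))
        psi = (a_t / a_t[t_peak])[:, None]
        phi = np.zeros(tmpl.phi_c.shape)
        for c in range(2):
            coef = scipy.sparse.linalg.lsqr(bs, truth.motion.d[t_peak, c].ravel())[0]
            phi[c, :, :, 0] = coef.reshape(16, 16)
        f_truth, _ = fn(fn.pack(phi, psi))
        f_zero, _ = fn(fn.pack(np.zeros_like(phi), np.zeros_like(psi)))
        assert f_truth < f_zero

    def test_scale_ambiguity_leaves_objective_invariant(self, rng):
        fn, tmpl, *_ = self._problem(rng, rank=1)
        phi = rng.uniform(-0.3, 0.3, tmpl.phi_c.shape)
        psi = rng.uniform(-1.0, 1.0, tmpl.psi_c.shape)
        f1, _ = fn(fn.pack(phi, psi))
        a = 3.7
        f2, _ = fn(fn.pack(a * phi, psi / a))
        assert f2 == pytest.approx(f1, rel=1e-9)


class TestSolveMotion:
    def test_translation_recovery_subvoxel(self):
        # pure global translation (3 voxels), fully sampled, noiseless
        cfg = PhantomConfig(
            n_frames=16, nx=64, ny=64, n_coils=3, cardiac_amplitude_vox=0.0,
            resp_amplitude_vox=3.0, resp_period_s=0.8, sampling_scheme="full",
            readouts_per_frame=64, noise_sigma=0.0, seed=5,
        )
        truth = generate_phantom(cfg)
        maps = make_coil_maps(truth.grid, 3)
        ks = simulate_kspace(truth, maps, cfg)
        q = generate_phantom(cfg.replace(resp_amplitude_vox=0.0)).frames.astype(complex)
        rc = ReconConfig(rank_d=1, spatial_controls=24, precision="double")
        model = solve_motion(q, ks, maps, rc, seed=0)
        myo = truth.labels == LABELS["myocardium"]
        err = mtr.epe(model.expand(), truth.motion.d, mask=myo)
        assert err["mean"] < 0.3

    def test_zero_motion_recovered_as_null_field(self):
        cfg = PhantomConfig(
            n_frames=10, nx=48, ny=48, n_coils=3, cardiac_amplitude_vox=0.0,
            sampling_scheme="full", readouts_per_frame=48, noise_sigma=0.0, seed=6,
        )
        truth = generate_phantom(cfg)
        maps = make_coil_maps(truth.grid, 3)
        ks = simulate_kspace(truth, maps, cfg)
        rc = ReconConfig(rank_d=1, spatial_controls=24, precision="double")
        model = solve_motion(truth.frames.astype(complex), ks, maps, rc, seed=0)
        d = model.expand()
        body = truth.labels[0] > 0
        rms = float(np.sqrt((d**2).sum(axis=1)[:, body].mean()))
        assert rms < 0.1

    def test_same_seed_same_output(self, small_study):
        ks, maps, truth = small_study
        rc = ReconConfig(rank_d=1, spatial_controls=12, max_iter_motion=5)
        m1 = solve_motion(truth.frames.astype(complex), ks, maps, rc, seed=3)
        m2 = solve_motion(truth.frames.astype(complex), ks, maps, rc, seed=3)
        np.testing.assert_array_equal(m1.phi_c, m2.phi_c)
        np.testing.assert_array_equal(m1.psi_c, m2.psi_c)


class TestFrequencySplit:
    def _two_tone_model(self, grid, M=64, dt=0.05, sign=1.0):
        model = LowRankMotionModel.zeros(grid, M, 2, 8)
        rng = np.random.default_rng(0)
        model.phi_c[:, :, :, 0] = rng.standard_normal((2, 8, 8))
        model.phi_c[:, :, :, 1] = rng.standard_normal((2, 8, 8))
        t = np.arange(M) * dt
        model.psi_c[:, 0] = sign * np.sin(2 * np.pi * 1.0 * t)  # cardiac-like, 1 Hz
        model.psi_c[:, 1] = np.sin(2 * np.pi * 0.25 * t)  # respiratory-like
        return model

    def test_two_tone_partition(self, grid16):
        model = self._two_tone_model(grid16)
        split = frequency_split(model, cutoff_hz=0.5, frame_interval_s=0.05)
        assert len(split.low) == 1 and len(split.high) == 1
        # reconstructed groups sum to the full fields
        full = model.expand()
        np.testing.assert_allclose(
            split.low_fields.d + split.high_fields.d, full, atol=1e-8
        )

    def test_partition_invariant_to_sign_flips(self, grid16):
        a = frequency_split(self._two_tone_model(grid16), 0.5, 0.05)
        b = frequency_split(self._two_tone_model(grid16, sign=-1.0), 0.5, 0.05)
        assert a.low == b.low and a.high == b.high

    def test_mixed_components_are_unmixed_before_classification(self, grid16):
        model = self._two_tone_model(grid16)
        # rotate (Phi, Psi) by an invertible mixing: D is unchanged, raw columns
        # are two-tone mixtures
        v = np.array([[0.8, 0.6], [-0.6, 0.8]]) @ np.diag([1.3, 0.7])
        mixed = LowRankMotionModel(
            grid=model.grid, n_frames=model.n_frames,
            phi_c=np.tensordot(model.phi_c, np.linalg.inv(v).T, axes=([3], [0])),
            psi_c=model.psi_c @ v,
            spatial_controls=model.spatial_controls,
        )
        np.testing.assert_allclose(mixed.expand(), model.expand(), atol=1e-10)
        split = frequency_split(mixed, cutoff_hz=0.5, frame_interval_s=0.05)
        assert len(split.low) == 1 and len(split.high) == 1
        ref = frequency_split(model, cutoff_hz=0.5, frame_interval_s=0.05)
        np.testing.assert_allclose(split.low_fields.d, ref.low_fields.d, atol=1e-6)

    def test_static_component_classified_low(self, grid16):
        model = LowRankMotionModel.zeros(grid16, 32, 1, 6)
        model.phi_c[0, :, :, 0] = 1.0
        model.psi_c[:, 0] = 2.0  # constant in time
        split = frequency_split(model, 0.5, 0.05)
        assert split.low == [0] and split.high == []

    def test_cutoff_outside_band_rejected(self, grid16):
        model = LowRankMotionModel.zeros(grid16, 32, 1, 6)
        with pytest.raises(ValueError):
            frequency_split(model, 15.0, 0.05)
        with pytest.raises(ValueError):
            frequency_split(model, 0.0, 0.05)
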