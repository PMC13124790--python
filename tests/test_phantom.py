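"""Phantom physics, geometry/motion consistency and k-space simulation."""

import numpy as np
import pytest
import scipy.integrate

from cmrmotus import metrics as mtr
from cmrmotus.containers import ImageGrid
from cmrmotus.operators import ifft2c
from cmrmotus.phantom import (
    GOLDEN_ANGLE_DEG,
    LABELS,
    PhantomConfig,
    bolus_auc,
    bolus_concentration,
    generate_phantom,
    make_coil_maps,
    make_sampling,
    saturation_recovery_signal,
    simulate_kspace,
)


class TestSaturationRecovery:
    def test_closed_form_value(self):
        # M0=1, T1=1000 ms, Tsat=150 ms, flip=15 degrees
        expected = np.sin(np.deg2rad(15.0)) * (1.0 - np.exp(-0.15))
        assert saturation_recovery_signal(1.0, 1000.0, 150.0, 15.0) == pytest.approx(expected)

    def test_limits_and_monotonicity(self):
        # T1 -> infinity kills the signal; Tsat >> T1 saturates at M0 sin(flip)
        assert saturation_recovery_signal(1.0, 1e12, 150.0, 15.0) == pytest.approx(0.0, abs=1e-9)
        assert saturation_recovery_signal(2.0, 100.0, 1e6, 30.0) == pytest.approx(
            2.0 * np.sin(np.deg2rad(30.0))
        )
        tsats = np.array([50.0, 150.0, 450.0])
        s = saturation_recovery_signal(1.0, 1000.0, tsats, 15.0)
        assert (np.diff(s) > 0).all()
        t1s = np.array([400.0, 1000.0, 1600.0])
        s = saturation_recovery_signal(1.0, t1s, 150.0, 15.0)
        assert (np.diff(s) < 0).all()

    def test_nonpositive_t1_rejected(self):
        with pytest.raises(ValueError):
            saturation_recovery_signal(1.0, -5.0, 150.0, 15.0)


class TestBolus:
    def test_zero_before_onset_and_nonnegative(self):
        cfg = PhantomConfig()
        t = np.linspace(0.0, 30.0, 601)
        for name in ("rv_blood", "lv_blood", "myocardium"):
            c = bolus_concentration(t, name, cfg)
            onset = cfg.bolus[name][0]
            assert (c[t <= onset] == 0).all()
            assert (c >= 0).all()

    def test_first_pass_peak_ordering(self):
        cfg = PhantomConfig()
        t = np.linspace(0.0, 30.0, 601)
        peaks = {
            name: t[np.argmax(bolus_concentration(t, name, cfg))]
            for name in ("rv_blood", "lv_blood", "myocardium")
        }
        assert peaks["rv_blood"] < peaks["lv_blood"] < peaks["myocardium"]

    def test_auc_matches_quadrature(self):
        cfg = PhantomConfig()
        quad, _ = scipy.integrate.quad(
            lambda t: float(bolus_concentration(np.array(t), "lv_blood", cfg)),
            0.0, 500.0, limit=200,
        )
        assert quad == pytest.approx(bolus_auc("lv_blood", cfg), rel=1e-2)

    def test_negative_shape_rejected(self):
        with pytest.raises(ValueError):
            PhantomConfig(bolus={"lv_blood": (8.0, -3.0, 2.0, 4.0)})


class TestCoilMaps:
    def test_single_coil_is_uniform(self, grid16):
        maps = make_coil_maps(grid16, 1)
        np.testing.assert_array_equal(maps.maps, np.ones((1, 16, 16)))

    def test_deterministic_and_smooth_coverage(self, grid32):
        a = make_coil_maps(grid32, 6)
        b = make_coil_maps(grid32, 6)
        np.testing.assert_array_equal(a.maps, b.maps)
        rss = a.rss()
        # coverage over the central body region is well above zero
        assert rss[8:24, 8:24].min() > 0.1 * rss.max()

    def test_zero_coils_rejected(self, grid16):
        with pytest.raises(ValueError):
            make_coil_maps(grid16, 0)


class TestSampling:
    def test_cartesian_line_counts(self, grid32):
        mask = make_sampling("cartesian_pseudorandom", 3, 12, grid32, seed=0)
        rows = mask[:, 0]
        assert mask.sum() == 12 * 32
        assert (mask == rows[:, None]).all()  # full lines
        full = make_sampling("cartesian_pseudorandom", 0, 32, grid32, seed=0)
        assert full.all()

    def test_cartesian_center_always_sampled_and_remainder_redrawn(self, grid32):
        m1 = make_sampling("cartesian_pseudorandom", 0, 8, grid32, seed=5, center_lines=4)
        m2 = make_sampling("cartesian_pseudorandom", 1, 8, grid32, seed=5, center_lines=4)
        center = np.array([-2, -1, 0, 1]) % 32
        assert m1[center].all() and m2[center].all()
        assert (m1 != m2).any()  # pseudo-random remainder differs across frames
        np.testing.assert_array_equal(
            m1, make_sampling("cartesian_pseudorandom", 0, 8, grid32, seed=5, center_lines=4)
        )

    def test_too_many_readouts_rejected(self, grid32):
        with pytest.raises(ValueError):
            make_sampling("cartesian_pseudorandom", 0, 33, grid32, seed=0)

    def test_golden_angle_increment(self, grid32):
        c0 = make_sampling("radial_golden_angle", 0, 4, grid32, seed=0)
        n = 32
        spokes = c0.reshape(4, n, 2)
        angles = np.rad2deg(np.arctan2(spokes[:, -1, 1], spokes[:, -1, 0]))
        diffs = np.diff(angles) % 180.0
        np.testing.assert_allclose(diffs, GOLDEN_ANGLE_DEG % 180.0, atol=1e-6)
        # spokes continue across frames
        c1 = make_sampling("radial_golden_angle", 1, 4, grid32, seed=0)
        a_last = np.arctan2(c0.reshape(4, n, 2)[-1, -1, 1], c0.reshape(4, n, 2)[-1, -1, 0])
        a_next = np.arctan2(c1.reshape(4, n, 2)[0, -1, 1], c1.reshape(4, n, 2)[0, -1, 0])
        assert (np.rad2deg(a_next - a_last) % 180.0) == pytest.approx(
            GOLDEN_ANGLE_DEG % 180.0, abs=1e-6
        )


class TestPhantomGeneration:
    def test_default_config_reproduces_study_dimensions(self):
        cfg = PhantomConfig()
        assert cfg.n_frames == 600
        assert (cfg.ny, cfg.nx) == (100, 100)
        assert cfg.frames_per_cycle == pytest.approx(20.0)  # 1 s / 50 ms
        assert cfg.tsat_ms == 150.0 and cfg.flip_deg == 15.0 and cfg.n_coils == 8

    def test_zero_motion_config_freezes_geometry(self):
        cfg = PhantomConfig(
            n_frames=6, nx=32, ny=32, cardiac_amplitude_vox=0.0,
            resp_amplitude_vox=0.0, seed=0,
        )
        truth = generate_phantom(cfg)
        assert np.all(truth.motion.d == 0)
        for t in range(1, 6):
            np.testing.assert_array_equal(truth.labels[t], truth.labels[0])

    def test_labels_disjoint_and_motion_consistent(self):
        # one heart beat at the native 100x100 resolution of the study
        cfg = PhantomConfig(n_frames=20, seed=7)
        truth = generate_phantom(cfg)
        assert set(np.unique(truth.labels)) <= set(LABELS.values())
        myo0 = (truth.labels[0] == LABELS["myocardium"]).astype(np.int32)
        warped = mtr.warp_segmentation(myo0, truth.motion)
        for t in range(truth.n_frames):
            d = mtr.dice(warped[t] > 0, truth.labels[t] == LABELS["myocardium"])
            assert d >= 0.95

    def test_determinism(self):
        cfg = PhantomConfig(n_frames=4, nx=32, ny=32, seed=3)
        a = generate_phantom(cfg)
        b = generate_phantom(cfg)
        np.testing.assert_array_equal(a.frames, b.frames)
        np.testing.assert_array_equal(a.motion.d, b.motion.d)

    def test_excessive_motion_rejected(self):
        with pytest.raises(ValueError, match="field of view"):
            generate_phantom(PhantomConfig(nx=32, ny=32, n_frames=2, resp_amplitude_vox=20.0))


class TestSimulateKspace:
    def test_full_sampling_inverts_to_frames(self):
        cfg = PhantomConfig(
            n_frames=3, nx=32, ny=32, n_coils=1, sampling_scheme="full",
            readouts_per_frame=32, noise_sigma=0.0, seed=0,
        )
        truth = generate_phantom(cfg)
        maps = make_coil_maps(truth.grid, 1)
        ks = simulate_kspace(truth, maps, cfg)
        rec = ifft2c(ks.samples[:, 0])
        np.testing.assert_allclose(rec.real, truth.frames, atol=1e-10)

    def test_masked_output_zero_off_sampled_lines(self, small_study):
        ks, _, _ = small_study
        assert np.all(ks.samples[:, :, ~ks.masks[0]][0] == 0)
        assert ks.masks[0].sum() == 8 * 32

    def test_noise_rms_scales_linearly(self):
        cfg = PhantomConfig(
            n_frames=8, nx=32, ny=32, n_coils=2, sampling_scheme="full",
            readouts_per_frame=32, noise_sigma=0.0, seed=5,
        )
        truth = generate_phantom(cfg)
        maps = make_coil_maps(truth.grid, 2)
        clean = simulate_kspace(truth, maps, cfg).samples
        r1 = simulate_kspace(truth, maps, cfg, noise_sigma=1.0, seed=5).samples - clean
        r2 = simulate_kspace(truth, maps, cfg, noise_sigma=2.0, seed=5).samples - clean
        rms1 = np.sqrt(np.mean(np.abs(r1) ** 2))
        rms2 = np.sqrt(np.mean(np.abs(r2) ** 2))
        assert rms1 == pytest.approx(1.0, rel=0.05)
        assert rms2 / rms1 == pytest.approx(2.0, rel=0.05)

    def test_radial_simulation_matches_dft_on_cartesian_axis(self):
        # a spoke at angle 0 lies on the kx axis: values must match the FFT row
        cfg = PhantomConfig(
            n_frames=1, nx=16, ny=16, n_coils=1,
            sampling_scheme="radial_golden_angle", readouts_per_frame=1,
            noise_sigma=0.0, seed=0,
        )
        truth = generate_phantom(cfg)
        maps = make_coil_maps(truth.grid, 1)
        ks = simulate_kspace(truth, maps, cfg)
        from cmrmotus.operators import fft2c

        full = fft2c(truth.frames[0])
        kx = ks.coords[0, :, 0]
        expected = full[0, np.rint(kx).astype(int) % 16]
        np.testing.assert_allclose(ks.samples[0, 0], expected, atol=1e-9)
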