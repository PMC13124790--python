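"""Shared fixtures: small grids, phantoms and k-space data for fast tests."""

import numpy as np
import pytest

from cmrmotus.containers import CoilMaps, DynamicKSpace, ImageGrid
from cmrmotus.phantom import PhantomConfig, generate_phantom, make_coil_maps, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def grid16():
    return ImageGrid(nx=16, ny=16, dx=1.0, dy=1.0)


@pytest.fixture
def grid32():
    return ImageGrid(nx=32, ny=32, dx=2.5, dy=2.5)


@pytest.fixture
def random_kspace_16(rng, grid16):
    """Random 6-frame, 3-coil row-undersampled Cartesian data on a 16x16 grid."""
    M, C, n = 6, 3, 16
    masks = np.zeros((M, n, n), dtype=bool)
    for t in range(M):
        masks[t, rng.choice(n, 6, replace=False)] = True
    samples = (
        rng.standard_normal((M, C, n, n)) + 1j * rng.standard_normal((M, C, n, n))
    ) * masks[:, None]
    kspace = DynamicKSpace(grid=grid16, samples=samples, masks=masks)
    coil_maps = make_coil_maps(grid16, C)
    return kspace, coil_maps


@pytest.fixture(scope="session")
def small_phantom():
    """Cardiac-only 48x48 phantom, 20 frames (one heart beat), fully sampled."""
    config = PhantomConfig(
        n_frames=20,
        nx=48,
        ny=48,
        n_coils=4,
        sampling_scheme="full",
        readouts_per_frame=48,
        noise_sigma=0.0,
        seed=7,
    )
    return generate_phantom(config)


@pytest.fixture(scope="session")
def small_study():
    """Small undersampled study: kspace, coil maps and truth (32x32, 10 frames)."""
    config = PhantomConfig(
        n_frames=10,
        nx=32,
        ny=32,
        n_coils=3,
        readouts_per_frame=8,
        center_lines=2,
        seed=11,
    )
    return simulate(config)
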