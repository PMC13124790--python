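"""Analytic 2D short-axis first-pass-perfusion phantom.

A fully closed-form digital phantom of a free-running perfusion acquisition
(600 frames at 50 ms, 100x100 matrix, 1 s heart cycle, saturation-recovery
gradient-echo contrast with Tsat = 150 ms and a 15 degree flip, 8 coils,
pseudo-random Cartesian sampling with 12 readouts/frame), with exact analytic
anatomy, motion and ground truth:

* geometry: body ellipse, myocardial annulus, interior LV disc and an RV
  crescent, all defined by closed-form indicator functions;
* cardiac motion: a smooth periodic radial contraction about the LV centre;
  the *pull-back* displacement (frame-t coordinates to frame-0 coordinates) is
  specified in closed form, so ground-truth motion fields are exact;
* respiration / bulk: sinusoidal and step translations;
* contrast: gamma-variate bolus curves per compartment (RV before LV before
  myocardium) shortening T1 through the relaxivity r1, converted to signal by
  the saturation-recovery equation.

Labels at frame t are obtained by evaluating the frame-0 indicators at the
pulled-back coordinates, which makes segmentations and motion fields mutually
consistent by construction.  Intensities are in arbitrary proton-density-like
units (M0 of order 1000), the numeric range typical of simulated scanner data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .containers import CoilMaps, DynamicKSpace, ImageGrid, MotionFieldStack
from .operators import fft2c

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "LABELS",
    "PHANTOM_PRESETS",
    "saturation_recovery_signal",
    "bolus_concentration",
    "make_coil_maps",
    "make_sampling",
    "generate_phantom",
    "simulate_kspace",
    "simulate",
    "GOLDEN_ANGLE_DEG",
]

LABELS = {"background": 0, "body": 1, "myocardium": 2, "lv_blood": 3, "rv_blood": 4}

GOLDEN_ANGLE_DEG = 111.246


def _default_bolus() -> dict:
    # (onset s, shape alpha, scale beta s, peak concentration mmol/L)
    return {
        "rv_blood": (5.0, 2.5, 1.5, 5.0),
        "lv_blood": (8.0, 3.0, 2.0, 4.0),
        "myocardium": (12.0, 3.5, 3.5, 0.8),
    }


def _default_t1() -> dict:
    # baseline T1 at 1.5 T, milliseconds
    return {"lv_blood": 1650.0, "rv_blood": 1650.0, "myocardium": 1100.0, "body": 900.0}


def _default_m0() -> dict:
    return {"lv_blood": 1000.0, "rv_blood": 1000.0, "myocardium": 800.0, "body": 500.0}


@dataclass
class PhantomConfig:
    """Acquisition and anatomy parameters of the synthetic study."""

    n_frames: int = 600
    frame_interval_s: float = 0.05
    nx: int = 100
    ny: int = 100
    dx_mm: float = 2.5
    dy_mm: float = 2.5
    heart_period_s: float = 1.0
    tr_ms: float = 2.0
    tsat_ms: float = 150.0
    flip_deg: float = 15.0
    n_coils: int = 8
    cardiac_amplitude_vox: float = 3.5
    cardiac_duty: float = 0.4
    resp_amplitude_vox: float = 0.0
    resp_period_s: float = 4.0
    resp_direction: tuple = (0.0, 1.0)
    bulk_shifts: tuple = ()  # ((time_s, (dx_vox, dy_vox)), ...) step translations
    bolus: dict = field(default_factory=_default_bolus)
    r1_relaxivity: float = 5.0  # L mmol^-1 s^-1
    t1_ms: dict = field(default_factory=_default_t1)
    m0: dict = field(default_factory=_default_m0)
    edge_width_vox: float = 1.2  # partial-volume softening of tissue boundaries
    conserve_magnetization: bool = True  # scale frames by the analytic det
    # intra-tissue intensity texture (band-limited, advected with the motion);
    # real tissue is never flat, and flat regions would leave in-plane motion
    # unidentifiable there
    texture_amplitudes: dict = field(
        default_factory=lambda: {
            "body": 0.15, "myocardium": 0.08, "lv_blood": 0.05, "rv_blood": 0.05,
        }
    )
    texture_scale_vox: float = 6.0
    sampling_scheme: str = "cartesian_pseudorandom"
    readouts_per_frame: int = 12
    center_lines: int = 4
    noise_sigma: Optional[float] = None  # None: set for ~30 dB sample SNR
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1 or self.n_coils < 1:
            raise ValueError("frame and coil counts must be positive")
        if min(self.frame_interval_s, self.heart_period_s, self.resp_period_s) <= 0:
            raise ValueError("all periods must be positive")
        if not 0.0 < self.flip_deg <= 90.0:
            raise ValueError("flip angle must lie in (0, 90] degrees")
        if self.tsat_ms <= 0 or self.tr_ms <= 0:
            raise ValueError("timing parameters must be positive")
        if not 0.0 < self.cardiac_duty <= 1.0:
            raise ValueError("cardiac duty cycle must lie in (0, 1]")
        if self.readouts_per_frame < 1:
            raise ValueError("need at least one readout per frame")
        if self.noise_sigma is not None and self.noise_sigma < 0:
            raise ValueError("noise sigma must be nonnegative")
        for name, (onset, alpha, beta, peak) in self.bolus.items():
            if alpha <= 0 or beta <= 0:
                raise ValueError(f"bolus shape/scale for {name} must be positive")
            if peak < 0 or onset < 0:
                raise ValueError(f"bolus onset/peak for {name} must be nonnegative")

    @property
    def grid(self) -> ImageGrid:
        return ImageGrid(nx=self.nx, ny=self.ny, dx=self.dx_mm, dy=self.dy_mm)

    @property
    def frames_per_cycle(self) -> float:
        return self.heart_period_s / self.frame_interval_s

    def replace(self, **kwargs) -> "PhantomConfig":
        return dataclasses.replace(self, **kwargs)


# Acquisition presets of the reference experiments; test2 uses external in-vivo
# data and therefore has no phantom preset.
PHANTOM_PRESETS: dict[str, dict] = {
    "test1": dict(),
    "test3": dict(sampling_scheme="radial_golden_angle", readouts_per_frame=10, n_frames=300),
    "test4": dict(sampling_scheme="radial_golden_angle", readouts_per_frame=20, n_frames=800),
}


@dataclass
class PhantomTruth:
    """Noiseless frames, exact motion fields, labels and enhancement curves."""

    frames: np.ndarray  # (M, ny, nx) real
    labels: np.ndarray  # (M, ny, nx) uint8, codes in LABELS
    motion: MotionFieldStack  # pull-back displacement, frame-t -> frame-0
    curves: dict  # compartment -> concentration (mmol/L) per frame
    grid: ImageGrid
    config: PhantomConfig

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def label_mask(self, name: str, t: Optional[int] = None) -> np.ndarray:
        code = LABELS[name]
        return (self.labels == code) if t is None else (self.labels[t] == code)


def saturation_recovery_signal(m0, t1_ms, tsat_ms, flip_deg):
    """Saturation-recovery signal ``M0 sin(flip) (1 - exp(-Tsat/T1))``.

    Monotone increasing in Tsat and decreasing in T1.
    """
    t1 = np.asarray(t1_ms, dtype=np.float64)
    if np.any(t1 <= 0):
        raise ValueError("T1 must be positive")
    if np.any(np.asarray(tsat_ms) <= 0):
        raise ValueError("Tsat must be positive")
    return m0 * np.sin(np.deg2rad(flip_deg)) * (1.0 - np.exp(-np.asarray(tsat_ms) / t1))


def bolus_concentration(t, compartment: str, config: PhantomConfig):
    """Gamma-variate contrast concentration (mmol/L) of a compartment at ``t``.

    ``c(t) = peak * ((t-t0)/(alpha beta))^alpha * exp(alpha - (t-t0)/beta)``,
    peaking at ``t0 + alpha*beta``; zero before the onset ``t0`` and for
    compartments without a bolus (body, background).
    """
    t = np.asarray(t, dtype=np.float64)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    if compartment not in config.bolus:
        return np.zeros_like(t)
    onset, alpha, beta, peak = config.bolus[compartment]
    dt = np.maximum(t - onset, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = peak * (dt / (alpha * beta)) ** alpha * np.exp(alpha - dt / beta)
    return np.where(dt > 0, c, 0.0)


def bolus_auc(compartment: str, config: PhantomConfig) -> float:
    """Closed-form time integral of the gamma-variate bolus curve."""
    import scipy.special

    if compartment not in config.bolus:
        return 0.0
    _, alpha, beta, peak = config.bolus[compartment]
    return float(
        peak * np.exp(alpha) * (alpha * beta) ** (-alpha) * beta ** (alpha + 1)
        * scipy.special.gamma(alpha + 1)
    )


def make_coil_maps(grid: ImageGrid, n_coils: int) -> CoilMaps:
    """Smooth complex Gaussian-lobe sensitivities on a ring around the FOV.

    A single coil gives a uniform (all-ones) profile so the forward model
    reduces to plain Fourier sampling.  Deterministic given grid and count.
    """
    if n_coils < 1:
        raise ValueError("need at least one coil")
    ny, nx = grid.shape
    if n_coils == 1:
        return CoilMaps(np.ones((1, ny, nx), dtype=np.complex128), grid)
    x, y = grid.coordinates()
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    n = max(nx, ny)
    ring = 0.65 * n
    width = 0.45 * n
    maps = np.empty((n_coils, ny, nx), dtype=np.complex128)
    for k in range(n_coils):
        theta = 2.0 * np.pi * k / n_coils
        px = cx + ring * np.cos(theta)
        py = cy + ring * np.sin(theta)
        mag = np.exp(-((x - px) ** 2 + (y - py) ** 2) / (2.0 * width**2))
        phase = 0.7 * np.pi * ((x - cx) * np.cos(theta) + (y - cy) * np.sin(theta)) / n
        maps[k] = mag * np.exp(1j * phase)
    rss = np.sqrt((np.abs(maps) ** 2).sum(axis=0))
    maps /= rss.max()
    return CoilMaps(maps, grid)


def make_sampling(
    scheme: str,
    frame_index: int,
    readouts: int,
    grid: ImageGrid,
    seed: int,
    center_lines: int = 4,
):
    """Per-frame sampling: Cartesian line mask or radial spoke coordinates.

    Cartesian: ``readouts`` full k-space lines (rows), a fixed low-frequency
    block of ``center_lines`` plus a variable-density pseudo-random remainder
    (Gaussian density over ky, re-drawn per frame from a seeded generator), as
    is conventional for dynamic-contrast L+S sampling.  Returned as a boolean
    (ny, nx) mask in natural FFT order.

    Radial: ``readouts`` spokes continuing the golden-angle schedule
    (111.246 degrees) across frames, each with max(nx, ny) samples; returned as
    (S, 2) coordinates in cycles/FOV.
    """
    ny, nx = grid.shape
    if scheme in ("cartesian_pseudorandom", "full"):
        if readouts > ny:
            raise ValueError("more readouts than k-space lines")
        if scheme == "full" or readouts == ny:
            rows = np.arange(ny)
        else:
            ncenter = min(center_lines, readouts)
            center_freqs = np.arange(-(ncenter // 2), ncenter - ncenter // 2)
            center_rows = center_freqs % ny
            rest = np.setdiff1d(np.arange(ny), center_rows)
            rng = np.random.default_rng([seed, frame_index])
            freqs = (rest + ny // 2) % ny - ny // 2  # centered line frequencies
            density = np.exp(-0.5 * (freqs / (ny / 6.0)) ** 2)
            density /= density.sum()
            extra = rng.choice(rest, size=readouts - ncenter, replace=False, p=density)
            rows = np.concatenate([center_rows, extra])
        mask = np.zeros((ny, nx), dtype=bool)
        mask[rows] = True
        return mask
    if scheme == "radial_golden_angle":
        n = max(nx, ny)
        if readouts > n:
            raise ValueError("more spokes than readout lines")
        nr = n
        r = np.arange(nr) - nr // 2
        spokes = frame_index * readouts + np.arange(readouts)
        angles = np.deg2rad(GOLDEN_ANGLE_DEG) * spokes
        kx = np.concatenate([r * np.cos(a) for a in angles])
        ky = np.concatenate([r * np.sin(a) for a in angles])
        # clip tiny numeric overshoot at exactly the Nyquist edge
        kx = np.clip(kx, -nx / 2, nx / 2 - 1e-9)
        ky = np.clip(ky, -ny / 2, ny / 2 - 1e-9)
        return np.stack([kx, ky], axis=1)
    raise ValueError(f"unknown sampling scheme {scheme!r}")


# ----------------------------------------------------------------------------
# Anatomy and motion
# ----------------------------------------------------------------------------

def _geometry(config: PhantomConfig) -> dict:
    ny, nx = config.ny, config.nx
    s = min(nx, ny) / 100.0
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    return dict(
        body_center=(cx, cy),
        body_axes=(45.0 * s, 39.0 * s),
        heart_center=(cx + 5.0 * s, cy - 4.0 * s),
        lv_radius=11.0 * s,
        myo_radius=19.0 * s,
        rv_center_offset=(-17.0 * s, 4.0 * s),
        rv_radius=11.0 * s,
        rv_clip_radius=20.0 * s,
        # displacement profile peaks at the endocardium so the wall thickens
        # during systole, as in real cardiac mechanics
        motion_radius=11.0 * s,
        scale=s,
    )


def _cardiac_amplitude(t: np.ndarray, config: PhantomConfig) -> np.ndarray:
    """Raised-cosine systolic contraction pulse, zero at frame 0 (diastole)."""
    phase = np.mod(t / config.heart_period_s, 1.0)
    duty = config.cardiac_duty
    pulse = np.where(phase < duty, 0.5 * (1.0 - np.cos(2.0 * np.pi * phase / duty)), 0.0)
    return config.cardiac_amplitude_vox * pulse


def _radial_profile(rho: np.ndarray, rho_pk: float) -> np.ndarray:
    """Smooth radial displacement profile, peaking at 1 for rho = rho_pk."""
    u = rho / rho_pk
    return u * np.exp(0.5 * (1.0 - u**2))


def _translation(t: float, config: PhantomConfig) -> np.ndarray:
    direction = np.asarray(config.resp_direction, dtype=np.float64)
    nrm = np.linalg.norm(direction)
    direction = direction / nrm if nrm > 0 else direction
    shift = config.resp_amplitude_vox * np.sin(2.0 * np.pi * t / config.resp_period_s) * direction
    for t_start, (bx, by) in config.bulk_shifts:
        if t >= t_start:
            shift = shift + np.array([bx, by], dtype=np.float64)
    return shift


def _pullback_coords(t: float, config: PhantomConfig, geom: dict, x: np.ndarray, y: np.ndarray):
    """Map frame-t voxel coordinates to frame-0 coordinates (closed form).

    Returns the mapped coordinates and the analytic Jacobian determinant of the
    map (translation contributes 1; the radial part ``rho -> rho + a g(rho)``
    contributes ``(1 + a g'(rho)) (1 + a g(rho)/rho)`` in 2D).
    """
    hx, hy = geom["heart_center"]
    shift = _translation(t, config)
    xp = x - shift[0]
    yp = y - shift[1]
    rho = np.sqrt((xp - hx) ** 2 + (yp - hy) ** 2)
    a = float(_cardiac_amplitude(np.asarray(t), config))
    if a != 0.0:
        rho_pk = geom["motion_radius"]
        u = rho / rho_pk
        env = np.exp(0.5 * (1.0 - u**2))
        g_over_rho = env / rho_pk  # g(rho)/rho, finite at the centre
        g_prime = env * (1.0 - u**2) / rho_pk
        fac = 1.0 + a * g_over_rho
        xs = hx + (xp - hx) * fac
        ys = hy + (yp - hy) * fac
        det = (1.0 + a * g_prime) * fac
    else:
        xs, ys = xp, yp
        det = np.ones_like(rho)
    return xs, ys, det


def _smoothstep(u: np.ndarray) -> np.ndarray:
    t = np.clip(u + 0.5, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _compartment_weights(xs: np.ndarray, ys: np.ndarray, geom: dict, edge: float) -> dict:
    """Partial-volume weights of each compartment at the given coordinates.

    Boundaries are softened over ``edge`` voxels (smoothstep of the signed
    distance), emulating the band-limited partial-volume appearance of real MR
    magnitude images; ``edge -> 0`` recovers binary masks.
    """
    bx, by = geom["body_center"]
    ax, ay = geom["body_axes"]
    hx, hy = geom["heart_center"]
    rvx = hx + geom["rv_center_offset"][0]
    rvy = hy + geom["rv_center_offset"][1]
    e = max(edge, 1e-6)
    # approximate signed distance to the body ellipse
    r_ell = np.sqrt(((xs - bx) / ax) ** 2 + ((ys - by) / ay) ** 2)
    body_in = _smoothstep((1.0 - r_ell) * min(ax, ay) / e)
    rho = np.sqrt((xs - hx) ** 2 + (ys - hy) ** 2)
    rho_rv = np.sqrt((xs - rvx) ** 2 + (ys - rvy) ** 2)
    lv = _smoothstep((geom["lv_radius"] - rho) / e)
    heart_out = _smoothstep((geom["myo_radius"] - rho) / e)
    myo = np.clip(heart_out - lv, 0.0, 1.0)
    rv = (
        _smoothstep((geom["rv_radius"] - rho_rv) / e)
        * _smoothstep((rho - geom["rv_clip_radius"]) / e)
        * (1.0 - heart_out)
    )
    body = np.clip(body_in - heart_out - rv, 0.0, 1.0)
    return {
        "lv_blood": lv * body_in,
        "myocardium": myo * body_in,
        "rv_blood": rv * body_in,
        "body": body,
        "background": np.clip(1.0 - body_in, 0.0, 1.0),
    }


def _labels_from_weights(weights: dict) -> np.ndarray:
    names = ["background", "body", "myocardium", "lv_blood", "rv_blood"]
    stack = np.stack([weights[n] for n in names])
    codes = np.array([LABELS[n] for n in names], dtype=np.uint8)
    return codes[np.argmax(stack, axis=0)]


class _Texture:
    """Smooth analytic random-phase texture, evaluated at arbitrary coordinates.

    A sum of 12 seeded sinusoids with wavelengths around ``scale`` voxels,
    normalized to unit standard deviation.  Being a closed-form function of the
    (pulled-back) coordinates, the texture advects exactly with the motion.
    """

    def __init__(self, scale: float, seed: int, n_waves: int = 12):
        rng = np.random.default_rng([seed, 7741])
        k_mag = 2.0 * np.pi / (scale * rng.uniform(0.7, 1.6, n_waves))
        theta = rng.uniform(0.0, 2.0 * np.pi, n_waves)
        self.kx = k_mag * np.cos(theta)
        self.ky = k_mag * np.sin(theta)
        self.phase = rng.uniform(0.0, 2.0 * np.pi, n_waves)
        self.norm = np.sqrt(2.0 / n_waves)

    def __call__(self, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        out = np.zeros_like(xs)
        for kx, ky, ph in zip(self.kx, self.ky, self.phase):
            out += np.cos(kx * xs + ky * ys + ph)
        return self.norm * out


def _compartment_signal(t: np.ndarray, config: PhantomConfig) -> dict:
    """Per-compartment signal intensity over time (saturation recovery)."""
    out = {}
    for name in ("lv_blood", "rv_blood", "myocardium", "body"):
        c = bolus_concentration(t, name, config)
        r1_base = 1000.0 / config.t1_ms[name]  # 1/s
        t1_eff_ms = 1000.0 / (r1_base + config.r1_relaxivity * c)
        out[name] = saturation_recovery_signal(
            config.m0[name], t1_eff_ms, config.tsat_ms, config.flip_deg
        )
    return out


def generate_phantom(config: PhantomConfig) -> PhantomTruth:
    """Generate noiseless frames, exact motion fields, labels and curves.

    Deterministic given the configuration (the anatomy and motion are fully
    analytic; the seed only enters k-space sampling and noise).
    """
    geom = _geometry(config)
    grid = config.grid
    ny, nx = grid.shape

    # guard: anatomy (body ellipse plus the largest translation) must stay in FOV
    max_shift = abs(config.resp_amplitude_vox) + sum(
        np.hypot(bxy[0], bxy[1]) for _, bxy in config.bulk_shifts
    )
    bx, by = geom["body_center"]
    ax, ay = geom["body_axes"]
    if (
        bx - ax - max_shift < -0.5
        or bx + ax + max_shift > nx - 0.5
        or by - ay - max_shift < -0.5
        or by + ay + max_shift > ny - 0.5
    ):
        raise ValueError("motion amplitude too large: anatomy exits the field of view")

    x, y = grid.coordinates()
    times = np.arange(config.n_frames) * config.frame_interval_s
    signals = _compartment_signal(times, config)
    curves = {
        name: bolus_concentration(times, name, config)
        for name in ("rv_blood", "lv_blood", "myocardium")
    }

    frames = np.zeros((config.n_frames, ny, nx))
    labels = np.zeros((config.n_frames, ny, nx), dtype=np.uint8)
    d = np.zeros((config.n_frames, 2, ny, nx))
    texture = _Texture(config.texture_scale_vox, config.seed)
    for t_idx, t in enumerate(times):
        xs, ys, det = _pullback_coords(float(t), config, geom, x, y)
        weights = _compartment_weights(xs, ys, geom, config.edge_width_vox)
        labels[t_idx] = _labels_from_weights(weights)
        d[t_idx, 0] = xs - x
        d[t_idx, 1] = ys - y
        tex = texture(xs, ys)
        frame = np.zeros((ny, nx))
        for name in ("lv_blood", "myocardium", "rv_blood", "body"):
            amp = config.texture_amplitudes.get(name, 0.0)
            modulation = np.clip(1.0 + amp * tex, 0.2, None)
            frame += weights[name] * signals[name][t_idx] * modulation
        # conservation of magnetization: integrated intensity is preserved
        # under the deformation (the analytic det of the pull-back map);
        # disabled, intensities follow the tissue class only (no compression
        # brightening, as in simulators that map tissue parameters to signal)
        frames[t_idx] = frame * det if config.conserve_magnetization else frame
    return PhantomTruth(
        frames=frames,
        labels=labels,
        motion=MotionFieldStack(d, grid=grid),
        curves=curves,
        grid=grid,
        config=config,
    )


# ----------------------------------------------------------------------------
# k-space simulation
# ----------------------------------------------------------------------------

def _radial_dft(frame: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Exact (small-scale) DFT of one image at explicit k-space coordinates."""
    ny, nx = frame.shape
    x = np.arange(nx)
    y = np.arange(ny)
    ex = np.exp(-2j * np.pi * np.outer(coords[:, 0], x) / nx)
    ey = np.exp(-2j * np.pi * np.outer(coords[:, 1], y) / ny)
    return (ey * (frame @ ex.T).T).sum(axis=1) / np.sqrt(nx * ny)


def simulate_kspace(
    truth: PhantomTruth,
    coil_maps: CoilMaps,
    config: Optional[PhantomConfig] = None,
    noise_sigma: Optional[float] = None,
    seed: Optional[int] = None,
) -> DynamicKSpace:
    """Sample the phantom to undersampled multi-coil k-space.

    Per frame: coil-weight, Fourier transform, apply the sampling mask (or
    evaluate spokes by direct DFT), then add complex Gaussian noise of standard
    deviation sigma per sample (``E|n|^2 = sigma^2``).  ``sigma=None`` picks the
    value giving ~30 dB SNR on the sampled data.  Deterministic given the seed.
    """
    config = config or truth.config
    if noise_sigma is None:
        noise_sigma = config.noise_sigma
    if seed is None:
        seed = config.seed
    grid = truth.grid
    M = truth.n_frames
    C = coil_maps.n_coils
    scheme = config.sampling_scheme
    rng = np.random.default_rng([seed, 917])

    if scheme in ("cartesian_pseudorandom", "full"):
        ny, nx = grid.shape
        samples = np.zeros((M, C, ny, nx), dtype=np.complex128)
        masks = np.zeros((M, ny, nx), dtype=bool)
        for t in range(M):
            mask = make_sampling(
                scheme, t, config.readouts_per_frame, grid, seed, config.center_lines
            )
            masks[t] = mask
            z = fft2c(coil_maps.maps * truth.frames[t][None])
            samples[t] = z * mask[None]
        sigma = _resolve_sigma(noise_sigma, samples, masks=masks)
        if sigma > 0:
            for t in range(M):
                idx = masks[t]
                n = rng.standard_normal((C, int(idx.sum()), 2))
                samples[t][:, idx] += sigma / np.sqrt(2.0) * (n[..., 0] + 1j * n[..., 1])
        return DynamicKSpace(
            grid=grid,
            samples=samples,
            kind="cartesian",
            masks=masks,
            frame_interval_s=config.frame_interval_s,
        )
    if scheme == "radial_golden_angle":
        coords = np.stack(
            [
                make_sampling(scheme, t, config.readouts_per_frame, grid, seed)
                for t in range(M)
            ]
        )
        S = coords.shape[1]
        samples = np.zeros((M, C, S), dtype=np.complex128)
        for t in range(M):
            for c in range(C):
                samples[t, c] = _radial_dft(coil_maps.maps[c] * truth.frames[t], coords[t])
        sigma = _resolve_sigma(noise_sigma, samples)
        if sigma > 0:
            n = rng.standard_normal(samples.shape + (2,))
            samples = samples + sigma / np.sqrt(2.0) * (n[..., 0] + 1j * n[..., 1])
        return DynamicKSpace(
            grid=grid,
            samples=samples,
            kind="radial",
            coords=coords,
            frame_interval_s=config.frame_interval_s,
        )
    raise ValueError(f"unknown sampling scheme {scheme!r}")


def _resolve_sigma(noise_sigma, samples, masks=None, snr_db: float = 30.0) -> float:
    if noise_sigma is not None:
        if noise_sigma < 0:
            raise ValueError("noise sigma must be nonnegative")
        return float(noise_sigma)
    if masks is not None:
        vals = samples[np.broadcast_to(masks[:, None], samples.shape)]
    else:
        vals = samples.ravel()
    rms = float(np.sqrt(np.mean(np.abs(vals) ** 2))) if vals.size else 0.0
    return rms * 10.0 ** (-snr_db / 20.0)


def simulate(config: PhantomConfig):
    """Full study generation: truth, coil maps and undersampled k-space."""
    truth = generate_phantom(config)
    maps = make_coil_maps(truth.grid, config.n_coils)
    kspace = simulate_kspace(truth, maps, config)
    return kspace, maps, truth
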