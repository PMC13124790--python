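"""Core data containers for dynamic multi-coil MRI reconstruction.

Conventions used throughout the package
---------------------------------------
* Images are 2D arrays of shape ``(ny, nx)``; time series of images are stacked
  frames-first, shape ``(M, ny, nx)``.
* Spatial coordinates are 0-based and voxel-centered: ``x`` is the column index,
  ``y`` the row index.  Displacements are expressed in voxel units with component
  ordering ``(x-displacement, y-displacement)``.
* k-space arrays are stored in the natural (unshifted) FFT ordering; explicit
  sample coordinates are given in cycles per field-of-view, i.e. in
  ``[-N/2, N/2)``.
* The Casorati matrix of a series is the ``(M, N)`` reshape (frames x voxels).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "ImageGrid",
    "CoilMaps",
    "DynamicKSpace",
    "ReferenceSeries",
    "CineSeries",
    "MotionFieldStack",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when a container invariant is violated."""


def _require_finite(name: str, arr: np.ndarray) -> None:
    if not np.isfinite(arr).all():
        raise ValidationError(f"{name} contains NaN or Inf values")


@dataclass(frozen=True)
class ImageGrid:
    """Uniform 2D voxel grid.

    Parameters
    ----------
    nx, ny : int
        Number of voxels along x (columns) and y (rows); at least 8 each.
    dx, dy : float
        Voxel spacing in millimetres.
    """

    nx: int
    ny: int
    dx: float = 2.5
    dy: float = 2.5

    def __post_init__(self) -> None:
        if self.nx < 8 or self.ny < 8:
            raise ValidationError("grid must be at least 8x8 voxels")
        if self.dx <= 0 or self.dy <= 0:
            raise ValidationError("voxel spacings must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def n_voxels(self) -> int:
        return self.ny * self.nx

    def coordinates(self) -> tuple[np.ndarray, np.ndarray]:
        """Voxel-centre coordinate arrays ``(X, Y)``, each of shape (ny, nx)."""
        y, x = np.mgrid[0 : self.ny, 0 : self.nx]
        return x.astype(np.float64), y.astype(np.float64)


@dataclass(frozen=True)
class CoilMaps:
    """Static complex coil sensitivity maps, shape ``(n_coils, ny, nx)``."""

    maps: np.ndarray
    grid: ImageGrid

    def __post_init__(self) -> None:
        maps = np.asarray(self.maps)
        if maps.ndim != 3 or maps.shape[1:] != self.grid.shape:
            raise ValidationError(
                f"coil maps shape {maps.shape} does not match grid {self.grid.shape}"
            )
        if maps.shape[0] < 1:
            raise ValidationError("need at least one coil")
        _require_finite("coil maps", maps)
        if not np.iscomplexobj(maps):
            maps = maps.astype(np.complex128)
        object.__setattr__(self, "maps", maps)
        if self.rss().max() <= 0:
            raise ValidationError("coil maps have zero root-sum-of-squares everywhere")

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]

    def rss(self) -> np.ndarray:
        """Root-sum-of-squares magnitude, shape (ny, nx)."""
        return np.sqrt((np.abs(self.maps) ** 2).sum(axis=0))


@dataclass
class DynamicKSpace:
    """Per-frame undersampled multi-coil k-space.

    Two sampling regimes are supported:

    * ``kind="cartesian"`` -- ``samples`` has shape ``(M, C, ny, nx)`` holding the
      masked k-space on the full Cartesian grid (zeros off the sampled locations)
      and ``masks`` is a boolean ``(M, ny, nx)`` array, both in natural FFT order.
    * ``kind="radial"`` -- ``samples`` has shape ``(M, C, S)`` with explicit
      coordinates ``coords`` of shape ``(M, S, 2)`` in cycles/FOV (kx, ky).
    """

    grid: ImageGrid
    samples: np.ndarray
    kind: str = "cartesian"
    masks: Optional[np.ndarray] = None
    coords: Optional[np.ndarray] = None
    frame_interval_s: float = 0.05

    def __post_init__(self) -> None:
        self.samples = np.ascontiguousarray(self.samples)
        if not np.iscomplexobj(self.samples):
            raise ValidationError("k-space samples must be complex")
        _require_finite("k-space samples", self.samples)
        if self.frame_interval_s <= 0:
            raise ValidationError("frame interval must be positive")
        if self.kind == "cartesian":
            if self.masks is None:
                raise ValidationError("cartesian k-space requires masks")
            self.masks = np.asarray(self.masks, dtype=bool)
            if self.samples.ndim != 4 or self.samples.shape[2:] != self.grid.shape:
                raise ValidationError("cartesian samples must have shape (M, C, ny, nx)")
            if self.masks.shape != (self.n_frames,) + self.grid.shape:
                raise ValidationError("masks must have shape (M, ny, nx)")
            if self.n_coils < 1:
                raise ValidationError("need at least one coil")
            if not self.masks.any(axis=(1, 2)).all():
                raise ValidationError("every frame must contain at least one sample")
        elif self.kind == "radial":
            if self.coords is None:
                raise ValidationError("radial k-space requires sample coordinates")
            self.coords = np.asarray(self.coords, dtype=np.float64)
            if self.samples.ndim != 3:
                raise ValidationError("radial samples must have shape (M, C, S)")
            if self.coords.shape != (self.n_frames, self.samples.shape[2], 2):
                raise ValidationError("coords must have shape (M, S, 2)")
            if self.samples.shape[2] < 1:
                raise ValidationError("every frame must contain at least one sample")
            nyq = np.array([self.grid.nx / 2, self.grid.ny / 2])
            if (np.abs(self.coords) > nyq + 1e-9).any():
                raise ValidationError("sample coordinates exceed the grid Nyquist limit")
        else:
            raise ValidationError(f"unknown k-space kind {self.kind!r}")

    @property
    def n_frames(self) -> int:
        return self.samples.shape[0]

    @property
    def n_coils(self) -> int:
        return self.samples.shape[1]

    def gridded(self) -> "DynamicKSpace":
        """Grid radial samples onto the Cartesian grid by nearest-bin averaging.

        Samples falling into the same Cartesian cell are averaged; hit cells form
        the sampling mask.  Cartesian data are returned unchanged.
        """
        if self.kind == "cartesian":
            return self
        ny, nx = self.grid.shape
        M, C, S = self.samples.shape
        out = np.zeros((M, C, ny, nx), dtype=self.samples.dtype)
        masks = np.zeros((M, ny, nx), dtype=bool)
        for t in range(M):
            ix = np.rint(self.coords[t, :, 0]).astype(int) % nx
            iy = np.rint(self.coords[t, :, 1]).astype(int) % ny
            flat = iy * nx + ix
            count = np.bincount(flat, minlength=ny * nx)
            hit = count > 0
            for c in range(C):
                acc_r = np.bincount(flat, weights=self.samples[t, c].real, minlength=ny * nx)
                acc_i = np.bincount(flat, weights=self.samples[t, c].imag, minlength=ny * nx)
                vals = np.zeros(ny * nx, dtype=self.samples.dtype)
                vals[hit] = (acc_r[hit] + 1j * acc_i[hit]) / count[hit]
                out[t, c] = vals.reshape(ny, nx)
            masks[t] = hit.reshape(ny, nx)
        return DynamicKSpace(
            grid=self.grid,
            samples=out,
            kind="cartesian",
            masks=masks,
            frame_interval_s=self.frame_interval_s,
        )


def _as_series(name: str, arr: np.ndarray, grid: Optional[ImageGrid]) -> np.ndarray:
    arr = np.ascontiguousarray(arr)
    if arr.ndim != 3:
        raise ValidationError(f"{name} must have shape (M, ny, nx)")
    if grid is not None and arr.shape[1:] != grid.shape:
        raise ValidationError(f"{name} shape {arr.shape} does not match grid {grid.shape}")
    _require_finite(name, arr)
    return arr


@dataclass
class ReferenceSeries:
    """Contrast-varying motion-static reference images ``Q = L + S``.

    ``L`` and ``S`` are complex series of shape ``(M, ny, nx)``; the low-rank
    component L carries the slowly varying structure and S the residual sparse
    dynamics (contrast enhancement).  ``Q`` is always the elementwise sum.
    """

    L: np.ndarray
    S: np.ndarray
    grid: Optional[ImageGrid] = None

    def __post_init__(self) -> None:
        self.L = _as_series("L", self.L, self.grid)
        self.S = _as_series("S", self.S, self.grid)
        if self.L.shape != self.S.shape:
            raise ValidationError("L and S must have identical shapes")

    @property
    def Q(self) -> np.ndarray:
        return self.L + self.S

    @property
    def n_frames(self) -> int:
        return self.L.shape[0]

    def casorati(self) -> np.ndarray:
        """Q reshaped to the (M, N) Casorati matrix."""
        M = self.n_frames
        return self.Q.reshape(M, -1)


@dataclass
class CineSeries:
    """The motion-deformed image series ``h_t = q_t(D_t(r)) det(grad D_t)``."""

    H: np.ndarray
    grid: Optional[ImageGrid] = None

    def __post_init__(self) -> None:
        self.H = _as_series("H", self.H, self.grid)

    @property
    def n_frames(self) -> int:
        return self.H.shape[0]


@dataclass
class MotionFieldStack:
    """Dense displacement fields, shape ``(M, 2, ny, nx)`` in voxel units.

    Component 0 is the x (column) displacement, component 1 the y (row)
    displacement.  Fields are pull-back displacements: frame ``t`` is produced by
    sampling the reference image at ``r + D_t(r)``.
    """

    d: np.ndarray
    grid: Optional[ImageGrid] = None

    def __post_init__(self) -> None:
        self.d = np.ascontiguousarray(self.d)
        if self.d.ndim != 4 or self.d.shape[1] != 2:
            raise ValidationError("motion fields must have shape (M, 2, ny, nx)")
        if self.grid is not None and self.d.shape[2:] != self.grid.shape:
            raise ValidationError("motion field shape does not match grid")
        _require_finite("motion fields", self.d)

    @property
    def n_frames(self) -> int:
        return self.d.shape[0]

    def temporal_mean(self) -> np.ndarray:
        return self.d.mean(axis=0)

    def rms(self) -> float:
        """Root-mean-square displacement magnitude over all voxels and frames."""
        return float(np.sqrt((self.d**2).sum(axis=1).mean()))

    @classmethod
    def zeros(cls, n_frames: int, grid: ImageGrid, dtype=np.float64) -> "MotionFieldStack":
        return cls(np.zeros((n_frames, 2) + grid.shape, dtype=dtype), grid=grid)
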