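"""Quantitative validation: SSIM, end-point error, DICE, Tenengrad sharpness.

All metrics leave their inputs untouched.  SSIM and EPE can be restricted to a
mask (e.g. a myocardium segmentation); DICE follows the convention that two
empty masks agree perfectly.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import scipy.ndimage
from skimage.metrics import structural_similarity

from .containers import MotionFieldStack

__all__ = [
    "ssim_series",
    "epe",
    "dice",
    "warp_segmentation",
    "tenengrad",
    "tenengrad_series",
]


def _magnitude_stack(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x)
    return np.abs(x) if np.iscomplexobj(x) else np.ascontiguousarray(x, dtype=np.float64)


def _frame_masks(mask, n_frames: int, shape) -> Optional[np.ndarray]:
    if mask is None:
        return None
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim == 2:
        mask = np.broadcast_to(mask, (n_frames, *mask.shape))
    if mask.shape != (n_frames, *shape):
        raise ValueError("mask shape does not match the image series")
    if not mask.any(axis=(1, 2)).all():
        raise ValueError("mask is empty in at least one frame")
    return mask


def ssim_series(h: np.ndarray, h_ref: np.ndarray, mask=None) -> dict:
    """Per-frame structural similarity of two image series.

    Magnitudes are jointly normalized to [0, 1] by the larger of the two series
    maxima (keeping the metric symmetric), then scored with the standard SSIM
    (11x11 Gaussian window, sigma 1.5, K1 = 0.01, K2 = 0.03).  With a mask the
    per-frame value is the mean of the SSIM map over the mask.

    Returns a dict with ``per_frame``, ``mean`` and ``sd``.
    """
    a = _magnitude_stack(h)
    b = _magnitude_stack(h_ref)
    if a.shape != b.shape:
        raise ValueError("image series shapes differ")
    if a.ndim == 2:
        a, b = a[None], b[None]
    masks = _frame_masks(mask, a.shape[0], a.shape[1:])
    scale = max(a.max(), b.max())
    if scale <= 0:
        raise ValueError("images are identically zero")
    a = a / scale
    b = b / scale
    vals = np.empty(a.shape[0])
    for t in range(a.shape[0]):
        _, smap = structural_similarity(
            a[t],
            b[t],
            data_range=1.0,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            win_size=11,
            full=True,
        )
        vals[t] = smap[masks[t]].mean() if masks is not None else smap.mean()
    return {"per_frame": vals, "mean": float(vals.mean()), "sd": float(vals.std())}


def epe(d_pred, d_true, mask=None, spacing_mm: Optional[float] = None) -> dict:
    """End-point error between displacement stacks.

    Per voxel ``sqrt((Dx_p - Dx_t)^2 + (Dy_p - Dy_t)^2)`` in voxel units,
    averaged over the mask per frame.  With ``spacing_mm`` the means are also
    reported in millimetres (isotropic spacing assumed).
    """
    if isinstance(d_pred, MotionFieldStack):
        d_pred = d_pred.d
    if isinstance(d_true, MotionFieldStack):
        d_true = d_true.d
    d_pred = np.asarray(d_pred, dtype=np.float64)
    d_true = np.asarray(d_true, dtype=np.float64)
    if d_pred.shape != d_true.shape:
        raise ValueError("displacement stacks have different shapes")
    err = np.sqrt(((d_pred - d_true) ** 2).sum(axis=1))  # (M, ny, nx)
    masks = _frame_masks(mask, err.shape[0], err.shape[1:])
    if masks is None:
        per_frame = err.mean(axis=(1, 2))
    else:
        per_frame = np.array([err[t][masks[t]].mean() for t in range(err.shape[0])])
    out = {"per_frame": per_frame, "mean": float(per_frame.mean()), "sd": float(per_frame.std())}
    if spacing_mm is not None:
        out["per_frame_mm"] = per_frame * spacing_mm
        out["mean_mm"] = float(per_frame.mean() * spacing_mm)
    return out


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """DICE overlap ``2|A n B| / (|A| + |B|)``; 1.0 when both masks are empty."""
    a = np.asarray(mask_a)
    b = np.asarray(mask_b)
    if a.shape != b.shape:
        raise ValueError("masks have different shapes")
    for m in (a, b):
        if m.dtype != bool and not np.isin(m, (0, 1)).all():
            raise ValueError("masks must be binary")
    a = a.astype(bool)
    b = b.astype(bool)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def warp_segmentation(labels0: np.ndarray, motion) -> np.ndarray:
    """Warp a frame-0 label map along a displacement stack.

    Pull-back with nearest-neighbour interpolation (labels are categorical, so
    no determinant weighting); voxels mapping outside the FOV become background.
    Returns an integer stack ``(M, ny, nx)``.
    """
    if isinstance(motion, MotionFieldStack):
        motion = motion.d
    motion = np.asarray(motion)
    labels0 = np.asarray(labels0)
    if not np.issubdtype(labels0.dtype, np.integer):
        if not np.allclose(labels0, np.rint(labels0)):
            raise ValueError("label map must be integer-valued")
        labels0 = np.rint(labels0).astype(np.int32)
    M = motion.shape[0]
    ny, nx = labels0.shape
    y, x = np.mgrid[0:ny, 0:nx]
    out = np.zeros((M, ny, nx), dtype=labels0.dtype)
    for t in range(M):
        xi = np.rint(x + motion[t, 0]).astype(int)
        yi = np.rint(y + motion[t, 1]).astype(int)
        valid = (xi >= 0) & (xi < nx) & (yi >= 0) & (yi < ny)
        frame = np.zeros((ny, nx), dtype=labels0.dtype)
        frame[valid] = labels0[yi[valid], xi[valid]]
        out[t] = frame
    return out


def tenengrad(image: np.ndarray) -> float:
    """Reference-free sharpness: mean squared Sobel-gradient magnitude.

    Uses the unnormalized 3x3 Sobel kernels ([1,2,1] x [-1,0,1]); zero for a
    constant image and quadratic under intensity scaling.
    """
    img = _magnitude_stack(image)
    if img.ndim != 2:
        raise ValueError("tenengrad expects a single 2D image")
    gx = scipy.ndimage.sobel(img, axis=1, mode="nearest")
    gy = scipy.ndimage.sobel(img, axis=0, mode="nearest")
    return float((gx**2 + gy**2).mean())


def tenengrad_series(series: np.ndarray) -> dict:
    series = _magnitude_stack(series)
    vals = np.array([tenengrad(series[t]) for t in range(series.shape[0])])
    return {"per_frame": vals, "mean": float(vals.mean()), "sd": float(vals.std())}
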