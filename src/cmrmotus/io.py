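"""Self-describing HDF5 containers for data, ground truth and results.

Layout (schema version 1): groups ``/kspace``, ``/coils``, optional ``/truth``
and ``/meta``; complex arrays are stored as paired ``*_real`` / ``*_imag``
datasets at native precision so round trips are lossless.  Units and seed
provenance are stored as attributes.
"""

from __future__ import annotations

import json
import os
from typing import Optional

import h5py
import numpy as np

from .containers import CoilMaps, DynamicKSpace, ImageGrid, MotionFieldStack

__all__ = [
    "FormatError",
    "write_container",
    "read_container",
    "write_results",
    "read_results",
    "export_cine_nifti",
]

SCHEMA_VERSION = "1"


class FormatError(ValueError):
    """Raised when a file does not conform to the documented layout."""


def _write_complex(group: h5py.Group, name: str, arr: np.ndarray) -> None:
    group.create_dataset(f"{name}_real", data=np.ascontiguousarray(arr.real))
    group.create_dataset(f"{name}_imag", data=np.ascontiguousarray(arr.imag))


def _read_complex(group: h5py.Group, name: str) -> np.ndarray:
    try:
        re = group[f"{name}_real"][...]
        im = group[f"{name}_imag"][...]
    except KeyError as exc:
        raise FormatError(f"missing dataset {name!r} in {group.name}") from exc
    return re + 1j * im


def _check_force(path, force: bool) -> None:
    if os.path.exists(path) and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")


def _grid_attrs(grid: ImageGrid) -> dict:
    return dict(nx=grid.nx, ny=grid.ny, dx_mm=grid.dx, dy_mm=grid.dy)


def _grid_from_attrs(attrs) -> ImageGrid:
    try:
        return ImageGrid(
            nx=int(attrs["nx"]), ny=int(attrs["ny"]),
            dx=float(attrs["dx_mm"]), dy=float(attrs["dy_mm"]),
        )
    except KeyError as exc:
        raise FormatError("missing grid attributes") from exc


def write_container(
    path,
    kspace: DynamicKSpace,
    coil_maps: CoilMaps,
    truth=None,
    meta: Optional[dict] = None,
    force: bool = False,
) -> None:
    """Write a dataset container (k-space + coils + optional phantom truth)."""
    _check_force(path, force)
    with h5py.File(path, "w") as f:
        m = f.create_group("meta")
        m.attrs["schema_version"] = SCHEMA_VERSION
        m.attrs["displacement_units"] = "voxels"
        m.attrs["kspace_units"] = "cycles_per_fov"
        m.attrs.update(_grid_attrs(kspace.grid))
        m.attrs["frame_interval_s"] = kspace.frame_interval_s
        if meta:
            m.attrs["extra"] = json.dumps(meta)

        g = f.create_group("kspace")
        g.attrs["kind"] = kspace.kind
        _write_complex(g, "samples", kspace.samples)
        if kspace.kind == "cartesian":
            g.create_dataset("masks", data=kspace.masks)
        else:
            g.create_dataset("coords", data=kspace.coords)

        c = f.create_group("coils")
        _write_complex(c, "maps", coil_maps.maps)

        if truth is not None:
            tg = f.create_group("truth")
            tg.create_dataset("frames", data=truth.frames)
            tg.create_dataset("labels", data=truth.labels)
            tg.create_dataset("motion", data=truth.motion.d)
            tg.attrs["seed"] = int(truth.config.seed)
            cg = tg.create_group("curves")
            for name, curve in truth.curves.items():
                cg.create_dataset(name, data=curve)


def read_container(path):
    """Read a dataset container; returns (kspace, coil_maps, truth, meta).

    ``truth`` is ``None`` when the file carries no ground-truth block.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        if "meta" not in f or "kspace" not in f or "coils" not in f:
            raise FormatError("file is missing required groups (/meta, /kspace, /coils)")
        meta = dict(f["meta"].attrs)
        grid = _grid_from_attrs(f["meta"].attrs)
        dt = float(f["meta"].attrs.get("frame_interval_s", 0.05))

        g = f["kspace"]
        kind = g.attrs.get("kind", "cartesian")
        samples = _read_complex(g, "samples")
        if kind == "cartesian":
            if "masks" not in g:
                raise FormatError("cartesian container is missing /kspace/masks")
            kspace = DynamicKSpace(
                grid=grid, samples=samples, kind="cartesian",
                masks=g["masks"][...], frame_interval_s=dt,
            )
        else:
            if "coords" not in g:
                raise FormatError("radial container is missing /kspace/coords")
            kspace = DynamicKSpace(
                grid=grid, samples=samples, kind="radial",
                coords=g["coords"][...], frame_interval_s=dt,
            )
        coil_maps = CoilMaps(_read_complex(f["coils"], "maps"), grid)

        truth = None
        if "truth" in f:
            from .phantom import PhantomConfig, PhantomTruth

            tg = f["truth"]
            curves = {name: tg["curves"][name][...] for name in tg["curves"]}
            cfg = PhantomConfig(
                n_frames=samples.shape[0],
                frame_interval_s=dt,
                nx=grid.nx,
                ny=grid.ny,
                n_coils=coil_maps.n_coils,
                seed=int(tg.attrs.get("seed", 0)),
            )
            truth = PhantomTruth(
                frames=tg["frames"][...],
                labels=tg["labels"][...],
                motion=MotionFieldStack(tg["motion"][...], grid=grid),
                curves=curves,
                grid=grid,
                config=cfg,
            )
    return kspace, coil_maps, truth, meta


def write_results(path, results, force: bool = False) -> None:
    """Persist a :class:`~cmrmotus.model.CMRMotusResults` to HDF5."""
    _check_force(path, force)
    with h5py.File(path, "w") as f:
        m = f.create_group("meta")
        m.attrs["schema_version"] = SCHEMA_VERSION
        grid = results.model.kspace.grid
        m.attrs.update(_grid_attrs(grid))
        m.attrs["frame_interval_s"] = results.model.kspace.frame_interval_s

        g = f.create_group("recon")
        _write_complex(g, "L", results.L)
        _write_complex(g, "S", results.S)
        _write_complex(g, "H", results.H)

        mo = f.create_group("motion")
        mo.create_dataset("D", data=results.fields.d)
        mo.create_dataset("phi_c", data=results.motion_model.phi_c)
        mo.create_dataset("psi_c", data=results.motion_model.psi_c)
        mo.attrs["spatial_controls"] = results.motion_model.spatial_controls
        mo.attrs["temporal_controls"] = (
            -1
            if results.motion_model.temporal_controls is None
            else results.motion_model.temporal_controls
        )
        f.attrs["report"] = json.dumps(results.report)


def read_results(path) -> dict:
    """Load a results container into plain arrays plus the report dict."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        if "recon" not in f or "motion" not in f:
            raise FormatError("file is missing required groups (/recon, /motion)")
        grid = _grid_from_attrs(f["meta"].attrs)
        out = dict(
            L=_read_complex(f["recon"], "L"),
            S=_read_complex(f["recon"], "S"),
            H=_read_complex(f["recon"], "H"),
            D=f["motion"]["D"][...],
            phi_c=f["motion"]["phi_c"][...],
            psi_c=f["motion"]["psi_c"][...],
            grid=grid,
            frame_interval_s=float(f["meta"].attrs["frame_interval_s"]),
            report=json.loads(f.attrs["report"]),
        )
    return out


def export_cine_nifti(h: np.ndarray, grid: ImageGrid, path, force: bool = False) -> None:
    """Export a cine magnitude series as a NIfTI volume (x, y, 1, t)."""
    import nibabel as nib

    _check_force(path, force)
    mag = np.abs(np.asarray(h))
    vol = np.transpose(mag, (2, 1, 0))[:, :, None, :]
    affine = np.diag([grid.dx, grid.dy, 1.0, 1.0])
    nib.save(nib.Nifti1Image(vol.astype(np.float32), affine), str(path))
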