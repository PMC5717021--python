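"""Container I/O: Stokes volumes (NPZ/HDF5), birefringence maps, DOP TIFFs."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import tifffile

from .polarimetry import ScalarVolume, StokesVolume
from .texture import BirefringenceMap

__all__ = [
    "save_stokes",
    "load_stokes",
    "save_biref_tiff",
    "load_biref_tiff",
    "write_dop_tiff",
]

_HDF5_SUFFIXES = {".h5", ".hdf5"}


def save_stokes(path: str | Path, vol: StokesVolume) -> None:
    """Write a Stokes volume as NPZ (.npz) or HDF5 (.h5/.hdf5).

    Both layouts carry named I/Q/U/V datasets plus the voxel spacings.
    """
    path = Path(path)
    spacing = np.array([vol.spacing_z, vol.spacing_x, vol.spacing_y])
    if path.suffix in _HDF5_SUFFIXES:
        with h5py.File(path, "w") as f:
            for name in "IQUV":
                f.create_dataset(name, data=getattr(vol, name))
            f.attrs["spacing_z"] = vol.spacing_z
            f.attrs["spacing_x"] = vol.spacing_x
            f.attrs["spacing_y"] = vol.spacing_y
    elif path.suffix == ".npz":
        np.savez(
            path, I=vol.I, Q=vol.Q, U=vol.U, V=vol.V, spacing_zxy=spacing
        )
    else:
        raise ValueError(f"unsupported volume container: {path.suffix!r}")


def load_stokes(path: str | Path) -> StokesVolume:
    path = Path(path)
    if path.suffix in _HDF5_SUFFIXES:
        with h5py.File(path, "r") as f:
            return StokesVolume(
                I=f["I"][()],
                Q=f["Q"][()],
                U=f["U"][()],
                V=f["V"][()],
                spacing_z=float(f.attrs["spacing_z"]),
                spacing_x=float(f.attrs["spacing_x"]),
                spacing_y=float(f.attrs["spacing_y"]),
            )
    if path.suffix == ".npz":
        with np.load(path) as data:
            sz, sx, sy = data["spacing_zxy"]
            return StokesVolume(
                I=data["I"], Q=data["Q"], U=data["U"], V=data["V"],
                spacing_z=float(sz), spacing_x=float(sx), spacing_y=float(sy),
            )
    raise ValueError(f"unsupported volume container: {path.suffix!r}")


def save_biref_tiff(path: str | Path, bmap: BirefringenceMap) -> None:
    """Write a birefringence map as a float32 TIFF.

    2-D maps become one page; 3-D (z, x, y) maps one page per frame.
    The spacings are stored in the image description for round-tripping.
    """
    v = bmap.values.astype(np.float32)
    if v.ndim == 3:
        v = np.moveaxis(v, 2, 0)  # pages = frames
    desc = f"spacing_z={bmap.spacing_z};spacing_x={bmap.spacing_x};spacing_y={bmap.spacing_y}"
    tifffile.imwrite(path, v, photometric="minisblack", description=desc)


def load_biref_tiff(path: str | Path) -> BirefringenceMap:
    with tifffile.TiffFile(path) as tf:
        v = tf.asarray()
        desc = tf.pages[0].description or ""
    spacing = {"spacing_z": 1.0, "spacing_x": 1.0, "spacing_y": 1.0}
    for part in desc.split(";"):
        if "=" in part:
            key, _, val = part.partition("=")
            if key.strip() in spacing:
                spacing[key.strip()] = float(val)
    if v.ndim == 3:
        v = np.moveaxis(v, 0, 2)  # pages back to the frame axis
    return BirefringenceMap(values=v.astype(float), **spacing)


def write_dop_tiff(path: str | Path, dop: ScalarVolume) -> None:
    """Export a DOP volume as a multi-page float32 TIFF, one page per frame."""
    pages = np.moveaxis(dop.values.astype(np.float32), 2, 0)
    tifffile.imwrite(path, pages, photometric="minisblack",
                     description=f"dop;spacing_z={dop.spacing_z}")
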