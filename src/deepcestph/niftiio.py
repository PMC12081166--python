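"""NIfTI input/output and the offset sidecar convention.

Volumes are written with a diagonal affine carrying the voxel size in mm.
NIfTI has no convention for saturation offsets, so the offset list of a
4D CEST stack travels in a plain-text sidecar (one ppm value per line,
order = 4th-dimension order, water = 0).
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["read_nifti", "write_nifti", "read_offsets", "write_offsets"]


def write_nifti(path, grid: np.ndarray, voxel_size) -> None:
    """Write a 3D/4D volume; the 4th dimension (if any) is the offset axis."""
    vox = tuple(float(v) for v in voxel_size)
    if any(v <= 0 for v in vox):
        raise ValueError("voxel sizes must be positive")
    affine = np.diag([*vox, 1.0])
    img = nib.Nifti1Image(np.asarray(grid, dtype=np.float32), affine)
    zooms = vox + (1.0,) * (grid.ndim - 3)
    img.header.set_zooms(zooms)
    nib.save(img, str(path))


def read_nifti(path):
    """Read a volume; returns ``(data, voxel_size)`` with data as float64."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such NIfTI file: {p}")
    try:
        img = nib.load(str(p))
        data = np.asarray(img.dataobj, dtype=float)
        vox = tuple(float(z) for z in img.header.get_zooms()[:3])
    except Exception as exc:  # malformed header
        raise OSError(f"cannot read NIfTI file {p}: {exc}") from exc
    if any(v <= 0 for v in vox):
        raise OSError(f"non-positive voxel size in header of {p}")
    return data, vox


def write_offsets(path, offsets) -> None:
    np.savetxt(path, np.asarray(offsets, dtype=float), fmt="%.6f",
               header="saturation offsets, ppm (order = 4D volume order)")


def read_offsets(path) -> np.ndarray:
    return np.atleast_1d(np.loadtxt(path))
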