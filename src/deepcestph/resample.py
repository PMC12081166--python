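"""Multi-resolution resampling between the CEST grid and the 31P CSI grid.

Coarse chemical-shift-imaging voxels are modelled as point-spread-function
weighted averages of the fine grid:

* ``box`` — exact volume-overlap weighting (ideal rectangular voxel);
* ``gaussian`` — separable Gaussian PSF with FWHM equal to the coarse
  pitch per axis, emulating the leakage of zero-filled CSI.

Both grids share a physical frame anchored at the volume corner.  The same
weight machinery serves the phantom's 31P renderer and the evaluation
down-sampler, so the two paths agree bit-exactly.
"""

from __future__ import annotations

import numpy as np

__all__ = ["psf_weights_1d", "psf_downsample", "reslice_to_fine", "coarse_shape"]


def coarse_shape(fine_shape, fine_voxel, coarse_voxel):
    return tuple(int(np.ceil(n * f / c)) for n, f, c in
                 zip(fine_shape, fine_voxel, coarse_voxel))


def psf_weights_1d(n_fine: int, fine_pitch: float, coarse_pitch: float,
                   mode: str = "box") -> np.ndarray:
    """Weight matrix (n_coarse, n_fine) along one axis."""
    if coarse_pitch < fine_pitch:
        raise ValueError("coarse voxel must be >= fine voxel in every dimension")
    n_coarse = int(np.ceil(n_fine * fine_pitch / coarse_pitch))
    W = np.zeros((n_coarse, n_fine))
    fine_lo = np.arange(n_fine) * fine_pitch
    fine_hi = fine_lo + fine_pitch
    fine_mid = 0.5 * (fine_lo + fine_hi)
    for i in range(n_coarse):
        lo, hi = i * coarse_pitch, (i + 1) * coarse_pitch
        if mode == "box":
            W[i] = np.clip(np.minimum(hi, fine_hi) - np.maximum(lo, fine_lo),
                           0.0, None)
        elif mode == "gaussian":
            center = 0.5 * (lo + hi)
            W[i] = fine_pitch * np.exp(
                -4.0 * np.log(2.0) * ((fine_mid - center) / coarse_pitch) ** 2)
        else:
            raise ValueError(f"unknown psf mode {mode!r}")
    return W


def psf_downsample(values: np.ndarray, mask: np.ndarray,
                   fine_voxel, coarse_voxel, psf_mode: str = "box",
                   min_support: float = 0.5):
    """PSF-weighted, mask-aware downsampling.

    Weights are renormalized over in-mask fine voxels.  Coarse voxels
    whose in-mask weight fraction is below ``min_support`` (default 0.5)
    are dropped from the coarse mask — the analogue of excluding
    poorly-supported CSI voxels near the skull.

    Returns ``(coarse_values, coarse_mask)``; dropped voxels hold NaN.
    """
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if values.shape != mask.shape or values.ndim != 3:
        raise ValueError("values and mask must be matching 3D grids")
    Ws = [psf_weights_1d(values.shape[a], fine_voxel[a], coarse_voxel[a], psf_mode)
          for a in range(3)]

    def _apply(vol):
        out = np.tensordot(Ws[0], vol, axes=(1, 0))
        out = np.tensordot(Ws[1], out, axes=(1, 1)).transpose(1, 0, 2)
        out = np.tensordot(Ws[2], out, axes=(1, 2)).transpose(1, 2, 0)
        return out

    m = mask.astype(float)
    num = _apply(np.where(mask, values, 0.0))
    den = _apply(m)
    total = _apply(np.ones_like(m))
    with np.errstate(invalid="ignore", divide="ignore"):
        support = np.where(total > 0, den / total, 0.0)
        coarse = np.where(den > 0, num / den, np.nan)
    coarse_mask = (support >= min_support) & (den > 0)
    coarse = np.where(coarse_mask, coarse, np.nan)
    return coarse, coarse_mask


def reslice_to_fine(coarse_values: np.ndarray, coarse_mask: np.ndarray,
                    coarse_voxel, fine_shape, fine_voxel):
    """Nearest-coarse-voxel reslicing of a coarse map onto the fine grid.

    Each fine voxel takes the value of the coarse voxel containing its
    center (how a resliced CSI map presents on the imaging grid).
    Returns ``(fine_values, fine_valid)``.
    """
    idx = []
    for a in range(3):
        centers = (np.arange(fine_shape[a]) + 0.5) * fine_voxel[a]
        j = np.floor(centers / coarse_voxel[a]).astype(int)
        idx.append(np.clip(j, 0, coarse_values.shape[a] - 1))
    ix, iy, iz = np.meshgrid(*idx, indexing="ij")
    fine = coarse_values[ix, iy, iz]
    valid = np.asarray(coarse_mask, dtype=bool)[ix, iy, iz]
    return fine, valid
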