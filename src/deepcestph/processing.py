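"""Z-spectrum post-processing: normalization, B0 correction, CEST metrics.

Raw saturated volumes are normalized by the unsaturated M0 reference,
re-centered per voxel using a delta-B0 map (WASSR-style correction by
monotone cubic re-interpolation), and condensed into the classical amide
CEST metrics:

* MTR_asym(dw) = Z(-dw) - Z(+dw)                (APT-weighted asymmetry)
* MTR_rex(dw)  = 1/Z(+dw) - 1/Z(-dw)            (spillover-corrected)
* AREX(dw)     = MTR_rex(dw) / T1               (additionally T1-corrected)

The MTR_rex reference is the opposite-side Z value (asymmetry-based); a
Lorentzian-fit reference is a possible dialect, not implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = ["ZSpectrumVolume", "MetricMap", "normalize", "b0_correct",
           "mtr_asym", "mtr_asym_block", "mtr_rex", "arex"]


@dataclass
class ZSpectrumVolume:
    """Normalized 4D Z-spectrum data: ``z`` has shape (*grid, n_offsets)."""

    offsets: np.ndarray  # ppm, strictly ascending
    z: np.ndarray
    voxel_size: tuple
    mask: np.ndarray  # valid voxels

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        order = np.argsort(self.offsets)
        if not np.array_equal(order, np.arange(order.size)):
            self.offsets = self.offsets[order]
            self.z = self.z[..., order]
        if np.any(np.diff(self.offsets) <= 0):
            raise ValueError("offsets must be unique")
        if self.z.shape[-1] != self.offsets.size:
            raise ValueError("offset count mismatch")


@dataclass
class MetricMap:
    name: str  # MTR_asym | MTR_rex | AREX
    delta_omega: float  # ppm
    values: np.ndarray  # 3D
    mask: np.ndarray
    units: str = "dimensionless"


def normalize(raw_4d: np.ndarray, m0: np.ndarray, voxel_size=(3.0, 3.0, 4.0),
              offsets=None, mask=None, eps_frac: float = 1e-9) -> ZSpectrumVolume:
    """Z = raw / M0 per voxel and offset; voxels with negligible M0 are
    masked out rather than divided through."""
    raw_4d = np.asarray(raw_4d, dtype=float)
    m0 = np.asarray(m0, dtype=float)
    if raw_4d.shape[:-1] != m0.shape:
        raise ValueError("raw 4D and M0 grids do not match")
    if offsets is None:
        raise ValueError("offsets are required (sidecar of the 4D stack)")
    good = m0 > eps_frac * (m0.max() if m0.size else 0.0)
    if mask is not None:
        good = good & np.asarray(mask, dtype=bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(good[..., None], raw_4d / m0[..., None], 0.0)
    return ZSpectrumVolume(offsets=np.asarray(offsets, dtype=float), z=z,
                           voxel_size=tuple(voxel_size), mask=good)


def b0_correct(zvol: ZSpectrumVolume, db0_map: np.ndarray) -> ZSpectrumVolume:
    """Re-center each voxel's spectrum using its delta-B0 (ppm).

    The value measured at nominal offset w belongs at w - db0, so the
    corrected spectrum is the measured one re-interpolated at w + db0
    (monotone cubic).  Nominal offsets that would extrapolate take the
    nearest valid value.  db0 = 0 is the exact identity; non-finite db0
    masks the voxel.
    """
    db0 = np.asarray(db0_map, dtype=float)
    if db0.shape != zvol.z.shape[:-1]:
        raise ValueError("db0 map must live on the Z-spectrum grid")
    off = zvol.offsets
    half_range = (off.max() - off.min()) / 2.0
    out = zvol.z.copy()
    mask = zvol.mask.copy()
    vox = np.nonzero(mask)
    for i, j, k in zip(*vox):
        d = db0[i, j, k]
        if not np.isfinite(d):
            mask[i, j, k] = False
            continue
        if d == 0.0:
            continue
        if abs(d) >= half_range:
            mask[i, j, k] = False
            continue
        x = np.clip(off + d, off[0], off[-1])
        out[i, j, k] = PchipInterpolator(off, zvol.z[i, j, k])(x)
    return ZSpectrumVolume(offsets=off.copy(), z=out,
                           voxel_size=zvol.voxel_size, mask=mask)


def _z_at(zvol: ZSpectrumVolume, dw: float) -> np.ndarray:
    """Linear interpolation of Z at one offset, vectorized over voxels."""
    off = zvol.offsets
    if dw < off[0] or dw > off[-1]:
        raise ValueError(f"offset {dw} ppm outside sampled range")
    j = int(np.clip(np.searchsorted(off, dw) - 1, 0, off.size - 2))
    w = (dw - off[j]) / (off[j + 1] - off[j])
    return (1 - w) * zvol.z[..., j] + w * zvol.z[..., j + 1]


def mtr_asym(zvol: ZSpectrumVolume, delta_omega: float) -> MetricMap:
    """MTR_asym(dw) = Z(-dw) - Z(+dw); antisymmetric in dw."""
    vals = _z_at(zvol, -delta_omega) - _z_at(zvol, +delta_omega)
    return MetricMap("MTR_asym", delta_omega,
                     np.where(zvol.mask, vals, np.nan), zvol.mask.copy())


def mtr_asym_block(zvol: ZSpectrumVolume, start: float = 3.0,
                   stop: float = 4.0, step: float = 0.1) -> np.ndarray:
    """APT-weighted MTR_asym sampled at start:step:stop ppm (11 values for
    the 3:0.1:4 default), shape (*grid, n_points)."""
    dws = np.arange(start, stop + step / 2, step)
    block = np.stack([mtr_asym(zvol, dw).values for dw in dws], axis=-1)
    return block


def mtr_rex(zvol: ZSpectrumVolume, delta_omega: float,
            z_floor: float = 0.05) -> MetricMap:
    """Spillover-corrected inverse-Z difference 1/Z(+dw) - 1/Z(-dw).

    Voxels with either side below ``z_floor`` are spillover-dominated and
    are masked (and counted), not silently returned.
    """
    zp, zm = _z_at(zvol, +delta_omega), _z_at(zvol, -delta_omega)
    ok = zvol.mask & (zp > z_floor) & (zm > z_floor)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(ok, 1.0 / np.where(ok, zp, 1.0) - 1.0 / np.where(ok, zm, 1.0),
                        np.nan)
    m = MetricMap("MTR_rex", delta_omega, vals, ok)
    m.n_floored = int(np.count_nonzero(zvol.mask & ~ok))
    return m


def arex(mtr_rex_map: MetricMap, qt1_map: np.ndarray) -> MetricMap:
    """AREX = MTR_rex / T1 (1/s); non-positive T1 voxels are masked."""
    qt1 = np.asarray(qt1_map, dtype=float)
    ok = mtr_rex_map.mask & np.isfinite(qt1) & (qt1 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(ok, mtr_rex_map.values / np.where(ok, qt1, 1.0), np.nan)
    return MetricMap("AREX", mtr_rex_map.delta_omega, vals, ok, units="1/s")
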