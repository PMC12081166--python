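"""Variable-flip-angle (VFA) T1 mapping from two spoiled-GRE volumes.

Two SPGR magnitude images at distinct flip angles are linearized as
y = S/sin(a) versus x = S/tan(a); the slope equals E1 = exp(-TR/T1).
A per-voxel B1 scale (actual/nominal flip angle) can be applied to both
flip angles.  Ideal RF spoiling is assumed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["VfaConfig", "PROTOCOL_VFA", "spgr_signal", "vfa_fit"]


@dataclass(frozen=True)
class VfaConfig:
    fa1: float  # degrees
    fa2: float  # degrees
    tr: float  # s
    b1_scale: object = 1.0  # scalar or array broadcastable to the volumes

    def __post_init__(self) -> None:
        if not (0 < self.fa1 < self.fa2 < 90):
            raise ValueError("require 0 < fa1 < fa2 < 90 degrees")
        if self.tr <= 0:
            raise ValueError("TR must be > 0")

    @classmethod
    def from_dict(cls, d: dict) -> "VfaConfig":
        if d.get("preset") == "protocol_vfa":
            return PROTOCOL_VFA
        return cls(**d)


#: The 3-T protocol: FA 4 and 24 degrees, TR 16.4 ms.
PROTOCOL_VFA = VfaConfig(fa1=4.0, fa2=24.0, tr=0.0164)


def spgr_signal(m0, t1, fa_deg, tr):
    """Ideally spoiled gradient-echo signal.

    S = m0 * sin(fa) * (1 - E1) / (1 - E1 * cos(fa)), E1 = exp(-TR/T1).
    """
    t1 = np.asarray(t1, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("T1 must be > 0")
    fa = np.deg2rad(fa_deg)
    e1 = np.exp(-tr / t1)
    return m0 * np.sin(fa) * (1.0 - e1) / (1.0 - e1 * np.cos(fa))


def vfa_fit(s1, s2, config: VfaConfig):
    """Two-point VFA T1 fit.

    Returns ``(t1, m0, valid)``: T1 in seconds, proton-density-weighted
    amplitude, and a boolean mask of voxels whose linearized slope lies in
    (0, 1).  Degenerate voxels (zero signal, non-physical slope) are
    masked, never returned as negative T1.
    """
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if s1.shape != s2.shape:
        raise ValueError("signal volumes must share a shape")
    a1 = np.deg2rad(config.fa1) * np.asarray(config.b1_scale, dtype=float)
    a2 = np.deg2rad(config.fa2) * np.asarray(config.b1_scale, dtype=float)

    with np.errstate(divide="ignore", invalid="ignore"):
        y1, x1 = s1 / np.sin(a1), s1 / np.tan(a1)
        y2, x2 = s2 / np.sin(a2), s2 / np.tan(a2)
        dx = x2 - x1
        slope = (y2 - y1) / dx
        valid = (np.isfinite(slope) & (slope > 0.0) & (slope < 1.0)
                 & (np.abs(dx) > 0) & ((s1 > 0) | (s2 > 0)))
        t1 = np.where(valid, -config.tr / np.log(np.where(valid, slope, 0.5)), np.nan)
        intercept = y1 - slope * x1
        e1 = np.where(valid, slope, 0.5)
        m0 = np.where(valid, intercept / (1.0 - e1), np.nan)
    return t1, m0, valid
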