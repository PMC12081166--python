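"""Multi-resolution comparison of predicted pH maps against 31P truth.

High-resolution maps are brought to the coarse 31P grid with the same PSF
machinery the phantom uses, then compared with RMSE, SSIM, Pearson
correlation / R^2 and Bland-Altman statistics.  The metric ladder ranks
the network prediction against conventional CEST metrics (MTR_asym,
MTR_rex, AREX) and qT1 by their correlation with the coarse truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from skimage.metrics import structural_similarity

from .resample import psf_downsample

__all__ = ["EvalReport", "downsample_to_target", "rmse", "ssim",
           "correlation", "bland_altman", "metric_ladder", "evaluate_maps"]


@dataclass
class EvalReport:
    rmse: float
    ssim: float
    pearson_r: float
    r2: float
    ba_mean_diff: float
    ba_sd: float
    ba_loa_low: float
    ba_loa_high: float
    n_voxels: int
    scope: str = "volume"  # or "slice:<k>"


def downsample_to_target(map_hi: np.ndarray, mask_hi: np.ndarray,
                         hi_voxel, lo_voxel, psf_mode: str = "gaussian",
                         min_support: float = 0.5):
    """PSF-aware downsampling to the 31P grid (shared with the phantom's
    own 31P render path, so the two agree bit-exactly)."""
    return psf_downsample(map_hi, mask_hi, hi_voxel, lo_voxel,
                          psf_mode=psf_mode, min_support=min_support)


def _masked_pair(a, b, mask):
    mask = np.asarray(mask, dtype=bool) & np.isfinite(a) & np.isfinite(b)
    return np.asarray(a)[mask], np.asarray(b)[mask]


def rmse(a, b, mask):
    """Root-mean-square difference over the mask."""
    av, bv = _masked_pair(a, b, mask)
    if av.size == 0:
        raise ValueError("empty mask")
    return float(np.sqrt(np.mean((av - bv) ** 2)))


def ssim(a, b, mask, sigma: float = 1.5, data_range: float | None = None,
         slicewise: bool = True):
    """Mean local structural similarity over the mask.

    Standard SSIM with a Gaussian window (sd 1.5 voxels) and stabilization
    constants K1 = 0.01, K2 = 0.03.  By default it is computed per axial
    slice and mask-averaged (volume comparison of representative slices);
    ``slicewise=False`` uses a 3D window.  The dynamic range defaults to
    the pooled in-mask range of both maps (symmetric in the arguments);
    constant inputs fall back to a unit range, where the stabilization
    constants keep the index defined.  Coarse 31P grids can be smaller
    than the Gaussian window (11 voxels at sd 1.5); such maps fall back
    to the largest odd uniform window that fits.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    mask = np.asarray(mask, dtype=bool) & np.isfinite(a) & np.isfinite(b)
    if a.shape != b.shape:
        raise ValueError("maps must share a shape")
    if not mask.any():
        raise ValueError("empty mask")
    if data_range is None:
        lo = min(a[mask].min(), b[mask].min())
        hi = max(a[mask].max(), b[mask].max())
        data_range = float(hi - lo) if hi > lo else 1.0
    fill_a, fill_b = a[mask].mean(), b[mask].mean()
    af = np.where(mask, a, fill_a)
    bf = np.where(mask, b, fill_b)

    def _ssim_map(x, y):
        gauss_win = 2 * int(np.ceil(3 * sigma)) + 1
        if min(x.shape) >= gauss_win:
            kw = dict(gaussian_weights=True, sigma=sigma)
        else:
            win = min(x.shape)
            kw = dict(win_size=win if win % 2 else win - 1)
        return structural_similarity(x, y, use_sample_covariance=False,
                                     data_range=data_range, full=True, **kw)[1]

    if not slicewise:
        return float(_ssim_map(af, bf)[mask].mean())
    vals, weights = [], []
    for k in range(a.shape[2]):
        mk = mask[:, :, k]
        if not mk.any():
            continue
        vals.append(_ssim_map(af[:, :, k], bf[:, :, k])[mk].mean())
        weights.append(mk.sum())
    return float(np.average(vals, weights=weights))


def correlation(a, b, mask):
    """Pearson r and R^2 (squared Pearson r of the scatter)."""
    av, bv = _masked_pair(a, b, mask)
    if av.size < 3:
        raise ValueError("need at least 3 voxels for a correlation")
    if np.std(av) == 0 or np.std(bv) == 0:
        raise ValueError("correlation undefined for constant input")
    r = float(sstats.pearsonr(av, bv)[0])
    return r, r * r


def bland_altman(a, b, mask):
    """Bland-Altman agreement statistics of d = a - b.

    Returns ``(mean_diff, sd, loa_low, loa_high, pairs)`` with limits
    mean +- 1.96 sd (n-1 denominator) and the per-voxel
    (mean(a,b), difference) pairs for plotting.
    """
    av, bv = _masked_pair(a, b, mask)
    if av.size < 2:
        raise ValueError("need at least 2 voxels")
    d = av - bv
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    pairs = np.column_stack([(av + bv) / 2.0, d])
    return mean_diff, sd, mean_diff - 1.96 * sd, mean_diff + 1.96 * sd, pairs


def evaluate_maps(pred_lo, truth_lo, mask_lo, scope: str = "volume") -> EvalReport:
    """All comparison statistics of two coarse-grid maps in one report."""
    r, r2 = correlation(pred_lo, truth_lo, mask_lo)
    md, sd, lo, hi, _ = bland_altman(pred_lo, truth_lo, mask_lo)
    m = np.asarray(mask_lo, dtype=bool) & np.isfinite(pred_lo) & np.isfinite(truth_lo)
    return EvalReport(rmse=rmse(pred_lo, truth_lo, mask_lo),
                      ssim=ssim(pred_lo, truth_lo, mask_lo),
                      pearson_r=r, r2=r2, ba_mean_diff=md, ba_sd=sd,
                      ba_loa_low=lo, ba_loa_high=hi,
                      n_voxels=int(np.count_nonzero(m)), scope=scope)


def _znorm(v, mask):
    x = v[mask]
    return (v - x.mean()) / (x.std() if x.std() > 0 else 1.0)


def metric_ladder(pred_map: np.ndarray, metric_maps: dict, truth_lo: np.ndarray,
                  mask_hi: np.ndarray, truth_mask_lo: np.ndarray,
                  hi_voxel, lo_voxel, psf_mode: str = "gaussian") -> pd.DataFrame:
    """Rank prediction and conventional metrics by correlation with truth.

    Each high-resolution map (the network prediction plus the entries of
    ``metric_maps``, e.g. MTR_asym / MTR_rex / AREX / qT1) is downsampled
    to the 31P grid, z-score normalized over the shared coarse mask and
    correlated with the coarse truth.  Returns a DataFrame sorted by |r|
    descending; the z-normalization makes the ranking invariant to affine
    rescaling of any input map.
    """
    rows = []
    for name, vol in [("deepCEST_pH", pred_map), *metric_maps.items()]:
        ok = np.asarray(mask_hi, dtype=bool) & np.isfinite(vol)
        lo_map, lo_mask = downsample_to_target(vol, ok, hi_voxel, lo_voxel,
                                               psf_mode=psf_mode)
        m = lo_mask & np.asarray(truth_mask_lo, dtype=bool) & np.isfinite(truth_lo)
        r, r2 = correlation(_znorm(lo_map, m), _znorm(truth_lo, m), m)
        rows.append({"metric": name, "r": r, "abs_r": abs(r), "r2": r2,
                     "n_voxels": int(np.count_nonzero(m))})
    df = pd.DataFrame(rows).sort_values("abs_r", ascending=False)
    return df.reset_index(drop=True)
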