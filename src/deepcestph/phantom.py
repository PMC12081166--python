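"""Digital brain-tumor phantom and paired multi-resolution data synthesis.

The phantom is an ellipsoidal brain with CSF/GM/WM shells and an optional
spheroidal tumor (rim + necrotic core) in one hemisphere.  Each tissue
class carries relaxation parameters and exchanging pools; intracellular
pH is assigned per class with smooth within-class variation (a Gaussian
random field) and is elevated in the tumor.  From the phantom the module
renders an aligned dataset emulating the 3-T protocol:

* 4D CEST volumes (3 x 3 x 4 mm voxels) + unsaturated M0 reference,
* a smooth polynomial delta-B0 field (ppm),
* quantitative T1 (or a two-flip-angle spoiled-GRE pair),
* a coarse 31P pH map (30 x 30 x 25 mm voxels) with CSI point-spread
  blurring,
* a brain mask excluding CSF.

Per-voxel Z-spectra come from the Bloch-McConnell simulator through a
per-class lookup table over a fine pH grid, interpolated in offset
(monotone cubic) and pH (linear); the exact propagator remains the oracle
for this fast path in the test suite.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from scipy.interpolate import PchipInterpolator
from scipy.ndimage import binary_erosion, gaussian_filter, generate_binary_structure

from .bloch import OffsetSchedule, Pool, TissueParams, protocol_3t_schedule, simulate_zspectrum
from .phosphorus import HhCalibration, fit_pi_pcr_distance, hh_ph, ph_to_shift, synthesize_spectrum
from .resample import psf_downsample
from .t1map import PROTOCOL_VFA, spgr_signal

__all__ = [
    "BACKGROUND", "WM", "GM", "CSF", "TUMOR_RIM", "NECROTIC_CORE",
    "PhantomConfig", "DigitalPhantom", "AcquiredDataset",
    "build_phantom", "render_cest", "render_t1", "render_ph31p",
    "erode_mask", "simulate_dataset",
]

BACKGROUND, WM, GM, CSF, TUMOR_RIM, NECROTIC_CORE = 0, 1, 2, 3, 4, 5

#: tissue classes included in the analysis mask (CSF excluded)
MASK_CLASSES = (WM, GM, TUMOR_RIM, NECROTIC_CORE)


@dataclass
class PhantomConfig:
    """Geometry and tissue parameters of the digital phantom.

    Defaults emulate a head at 3 T: a 240 x 240 x 72 mm field of view on
    3 x 3 x 4 mm CEST voxels, per-class pH inside the physiological
    6.9-7.3 range with elevated tumor pH, literature-typical relaxation
    times, and a +-0.3 ppm smooth B0 offset field.
    """

    shape: tuple = (80, 80, 18)
    voxel_size: tuple = (3.0, 3.0, 4.0)  # mm
    brain_semiaxes: tuple = (105.0, 105.0, 33.0)  # mm
    csf_thickness: float = 3.0  # mm, outer shell
    gm_thickness: float = 9.0  # mm
    tumor_enabled: bool = True
    tumor_center_offset: tuple = (45.0, 0.0, 0.0)  # mm from brain center
    tumor_radius: float = 24.0  # mm, glioblastoma scale
    core_radius: float = 10.0  # mm
    # per-class means
    ph: dict = field(default_factory=lambda: {
        WM: 7.00, GM: 7.03, CSF: 7.10, TUMOR_RIM: 7.15, NECROTIC_CORE: 7.25})
    t1: dict = field(default_factory=lambda: {
        WM: 1.1, GM: 1.6, CSF: 4.3, TUMOR_RIM: 1.8, NECROTIC_CORE: 2.0})
    t2: dict = field(default_factory=lambda: {
        WM: 0.070, GM: 0.090, CSF: 2.0, TUMOR_RIM: 0.120, NECROTIC_CORE: 0.150})
    mt_fraction: dict = field(default_factory=lambda: {
        WM: 0.07, GM: 0.04, CSF: 0.0, TUMOR_RIM: 0.03, NECROTIC_CORE: 0.01})
    m0: dict = field(default_factory=lambda: {
        WM: 0.75, GM: 0.85, CSF: 1.0, TUMOR_RIM: 0.90, NECROTIC_CORE: 0.80})
    amide_fraction: float = 9.0e-4
    noe_fraction: float = 3.0e-3
    # within-class mobile-protein density variation (relative sd of the
    # amide/NOE fractions): mild in normal tissue, strong in tumor —
    # the concentration confound that degrades fraction-sensitive metrics
    protein_rel_sd: dict = field(default_factory=lambda: {
        WM: 0.10, GM: 0.10, CSF: 0.0, TUMOR_RIM: 0.35, NECROTIC_CORE: 0.35})
    protein_smooth_mm: float = 10.0
    # within-class T1 heterogeneity (relative sd), strong in tumor where
    # edema/infiltration make T1 spatially variable and a poor pH surrogate
    t1_rel_sd: dict = field(default_factory=lambda: {
        WM: 0.05, GM: 0.05, CSF: 0.0, TUMOR_RIM: 0.15, NECROTIC_CORE: 0.15})
    t1_smooth_mm: float = 12.0
    ph_noise_sd: float = 0.02  # within-class pH variation (GRF sd)
    ph_smooth_mm: float = 15.0  # GRF correlation length
    db0_amplitude: float = 0.3  # ppm, max |dB0| over the brain
    k_ref: float = 30.0  # amide rate at ph_ref, 1/s
    ph_ref: float = 7.0

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("ph", "t1", "t2", "mt_fraction", "m0", "protein_rel_sd",
                    "t1_rel_sd"):
            d[key] = {int(k): float(v) for k, v in d[key].items()}
        return d

    def config_hash(self) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


@dataclass
class DigitalPhantom:
    """Labelled 3D volume with ground-truth pH and B0 offset fields."""

    label_volume: np.ndarray  # int labels
    voxel_size: tuple  # mm
    class_params: dict  # label -> TissueParams (class-mean pH)
    ph_volume: np.ndarray  # pH units, NaN outside brain
    db0_volume: np.ndarray  # ppm
    protein_volume: np.ndarray  # relative amide/NOE fraction scale, ~1
    t1_volume: np.ndarray  # true per-voxel water T1, s
    config: PhantomConfig

    def brain_mask(self) -> np.ndarray:
        """All labelled (non-background) voxels, CSF included."""
        return self.label_volume != BACKGROUND

    def analysis_mask(self) -> np.ndarray:
        """Brain voxels excluding CSF (mask used for training/eval)."""
        return np.isin(self.label_volume, MASK_CLASSES)


@dataclass
class AcquiredDataset:
    """One aligned synthetic acquisition in a common physical frame."""

    cest_4d: np.ndarray  # (*shape, n_offsets) raw signal
    m0: np.ndarray
    offsets: np.ndarray  # ppm
    qt1: np.ndarray  # s
    vfa_pair: tuple | None
    db0: np.ndarray  # ppm
    ph31p: np.ndarray  # coarse grid, pH units (NaN where dropped)
    ph31p_mask: np.ndarray  # coarse grid
    coarse_voxel: tuple  # mm
    mask: np.ndarray  # eroded analysis mask, CEST grid
    truth_ph: np.ndarray  # CEST grid
    voxel_size: tuple  # mm
    seed: int
    config_hash: str

    def __post_init__(self) -> None:
        if self.cest_4d.shape[-1] != len(self.offsets):
            raise ValueError("cest_4d offset count must equal schedule length")
        if self.cest_4d.shape[:-1] != self.mask.shape:
            raise ValueError("grids must share the CEST voxel frame")


def _class_tissue(cfg: PhantomConfig, label: int) -> TissueParams:
    pools = []
    if label != CSF:
        pools.append(Pool("amide", +3.5, cfg.amide_fraction, 1.0, 30.0,
                          cfg.k_ref))
        if cfg.mt_fraction[label] > 0:
            pools.append(Pool("mt", -2.4, cfg.mt_fraction[label], 1.0, 1.0e5, 40.0))
        pools.append(Pool("noe", -3.5, cfg.noe_fraction, 1.0, 50.0, 20.0))
    return TissueParams(water_R1=1.0 / cfg.t1[label],
                        water_R2=1.0 / cfg.t2[label],
                        pools=pools, pH=cfg.ph[label])


def _ellipsoid_r2(coords, semiaxes):
    return sum((c / a) ** 2 for c, a in zip(coords, semiaxes))


def build_phantom(config: PhantomConfig | None = None, seed: int = 0) -> DigitalPhantom:
    """Deterministic phantom construction for a fixed seed.

    Raises
    ------
    ValueError
        If the configured tumor does not fit inside the brain.
    """
    cfg = config or PhantomConfig()
    if any(s < 16 for s in cfg.shape):
        raise ValueError("grid dimensions must be at least 16 per axis")
    rng = np.random.default_rng(seed)
    shape, vox = cfg.shape, cfg.voxel_size
    center = [(n - 1) / 2.0 * v for n, v in zip(shape, vox)]
    grids = np.meshgrid(*[np.arange(n) * v - c for n, v, c in
                          zip(shape, vox, center)], indexing="ij")

    labels = np.zeros(shape, dtype=np.int16)
    outer = _ellipsoid_r2(grids, cfg.brain_semiaxes) <= 1.0
    gm_ax = tuple(a - cfg.csf_thickness for a in cfg.brain_semiaxes)
    wm_ax = tuple(a - cfg.csf_thickness - cfg.gm_thickness for a in cfg.brain_semiaxes)
    gm_in = _ellipsoid_r2(grids, gm_ax) <= 1.0
    wm_in = _ellipsoid_r2(grids, wm_ax) <= 1.0
    labels[outer] = CSF
    labels[gm_in] = GM
    labels[wm_in] = WM

    if cfg.tumor_enabled:
        tc = cfg.tumor_center_offset
        extremes = [tuple(tc[a] + s * (cfg.tumor_radius if a == ax else 0.0)
                          for a in range(3))
                    for ax in range(3) for s in (-1, 1)]
        for p in extremes:
            if _ellipsoid_r2(p, cfg.brain_semiaxes) > 1.0:
                raise ValueError("tumor placement outside the brain")
        d2 = sum((g - c) ** 2 for g, c in zip(grids, tc))
        rim = (d2 <= cfg.tumor_radius ** 2) & np.isin(labels, (WM, GM))
        labels[rim] = TUMOR_RIM
        core = (d2 <= cfg.core_radius ** 2) & (labels == TUMOR_RIM)
        labels[core] = NECROTIC_CORE

    brain = labels != BACKGROUND
    ph = np.full(shape, np.nan)
    for lab, mean_ph in cfg.ph.items():
        ph[labels == lab] = mean_ph
    if cfg.ph_noise_sd > 0:
        sigma_vox = [cfg.ph_smooth_mm / v for v in vox]
        grf = gaussian_filter(rng.standard_normal(shape), sigma_vox)
        sd = grf[brain].std()
        if sd > 0:
            ph = ph + np.where(brain, grf / sd * cfg.ph_noise_sd, 0.0)

    protein = np.ones(shape)
    if any(v > 0 for v in cfg.protein_rel_sd.values()):
        sigma_vox = [cfg.protein_smooth_mm / v for v in vox]
        grf_p = gaussian_filter(rng.standard_normal(shape), sigma_vox)
        sd = grf_p[brain].std()
        if sd > 0:
            grf_p = grf_p / sd
            for lab, rel in cfg.protein_rel_sd.items():
                sel = labels == lab
                protein[sel] = np.clip(1.0 + rel * grf_p[sel], 0.2, None)

    t1_vol = np.zeros(shape)
    for lab, val in cfg.t1.items():
        t1_vol[labels == lab] = val
    if any(v > 0 for v in cfg.t1_rel_sd.values()):
        sigma_vox = [cfg.t1_smooth_mm / v for v in vox]
        grf_t = gaussian_filter(rng.standard_normal(shape), sigma_vox)
        sd = grf_t[brain].std()
        if sd > 0:
            grf_t = grf_t / sd
            for lab, rel in cfg.t1_rel_sd.items():
                sel = labels == lab
                t1_vol[sel] = np.clip(t1_vol[sel] * (1.0 + rel * grf_t[sel]),
                                      0.3, 6.0)

    x, y, z = (g / max(c, 1e-9) for g, c in zip(grids, center))
    coeffs = rng.uniform(-1.0, 1.0, size=7)
    db0 = (coeffs[0] + coeffs[1] * x + coeffs[2] * y + coeffs[3] * z
           + coeffs[4] * x * x + coeffs[5] * y * y + coeffs[6] * x * y)
    peak = np.abs(db0[brain]).max() if brain.any() else 0.0
    db0 = db0 / peak * cfg.db0_amplitude if (peak > 0 and cfg.db0_amplitude > 0) \
        else np.zeros(shape)

    params = {lab: _class_tissue(cfg, lab) for lab in cfg.ph}
    return DigitalPhantom(labels, tuple(vox), params, ph, db0, protein,
                          t1_vol, cfg)


# --------------------------------------------------------------------------
# CEST rendering via a per-class (pH x offset) lookup table

_PH_STEP = 0.02
_DENSE_STEP = 0.1
_DENSE_MARGIN = 0.6  # ppm beyond schedule range, covers |dB0| <= 0.45


def _dense_offsets(schedule: OffsetSchedule) -> np.ndarray:
    off = np.asarray(schedule.offsets)
    return np.arange(off.min() - _DENSE_MARGIN, off.max() + _DENSE_MARGIN + 1e-9,
                     _DENSE_STEP)


_PROTEIN_STEP = 0.3


def _scaled_fractions(tissue: TissueParams, scale: float) -> TissueParams:
    """Scale the mobile-protein pools (amide, NOE) by a density factor."""
    from dataclasses import replace as _rp
    pools = [_rp(p, fraction=p.fraction * scale) if p.name in ("amide", "noe")
             else p for p in tissue.pools]
    return TissueParams(tissue.water_R1, tissue.water_R2, pools, tissue.pH)


def _node_grid(values: np.ndarray, step: float) -> np.ndarray:
    """Interpolation nodes covering the value range with one spare node so
    that linear interpolation always has a right neighbor."""
    lo = np.floor(values.min() / step) * step
    hi = np.ceil(values.max() / step) * step + step
    return np.arange(lo, hi + 1e-9, step)


def _class_table(tissue: TissueParams, s_grid, ph_grid, t1_grid,
                 schedule: OffsetSchedule, dense: np.ndarray,
                 k_ref: float, ph_ref: float) -> np.ndarray:
    """Z table of shape (len(s_grid), len(ph_grid), len(t1_grid), len(dense))."""
    dense_sched = schedule.with_offsets(dense)
    ph_sensitive = any(p.name == "amide" for p in tissue.pools)
    out = np.empty((len(s_grid), len(ph_grid), len(t1_grid), dense.size))
    for u, t1 in enumerate(t1_grid):
        base = TissueParams(1.0 / t1, tissue.water_R2, tissue.pools, tissue.pH)
        if not ph_sensitive:
            row = simulate_zspectrum(base, dense_sched)
            out[:, :, u] = row
            continue
        for i, s in enumerate(s_grid):
            scaled = _scaled_fractions(base, s)
            for j, ph in enumerate(ph_grid):
                out[i, j, u] = simulate_zspectrum(
                    scaled.with_ph(ph, k_ref, ph_ref), dense_sched)
    return out


def render_cest(phantom: DigitalPhantom, schedule: OffsetSchedule | None = None,
                noise_sd: float = 0.005, seed: int = 0):
    """Render the raw 4D CEST stack and the unsaturated M0 reference.

    Per voxel the Z-spectrum of its tissue class is evaluated at the
    voxel's pH (amide rate from the base-catalyzed law) and read out at
    the nominal offsets shifted by the voxel's delta-B0.  Gaussian noise
    of sd ``noise_sd`` is added on the normalized Z scale before scaling
    by M0.  Deterministic for a fixed seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    schedule = schedule or protocol_3t_schedule()
    cfg = phantom.config
    offsets = np.asarray(schedule.offsets)
    shape = phantom.label_volume.shape
    dense = _dense_offsets(schedule)
    rendered = phantom.label_volume != BACKGROUND
    if rendered.any() and np.abs(phantom.db0_volume[rendered]).max() > _DENSE_MARGIN - 0.1:
        raise ValueError("dB0 field exceeds the rendering margin")

    z4d = np.zeros(shape + (offsets.size,))
    labels = phantom.label_volume
    for lab in np.unique(labels):
        if lab == BACKGROUND:
            continue
        vox = np.nonzero(labels == lab)
        ph_v = phantom.ph_volume[vox]
        db0_v = phantom.db0_volume[vox]
        s_v = phantom.protein_volume[vox]
        t1_v = phantom.t1_volume[vox]
        ph_grid = _node_grid(ph_v, _PH_STEP)
        s_grid = _node_grid(s_v, _PROTEIN_STEP)
        t1_step = max((t1_v.max() - t1_v.min()) / 2.0, 0.05)
        t1_grid = _node_grid(t1_v, t1_step)
        table = _class_table(phantom.class_params[lab], s_grid, ph_grid,
                             t1_grid, schedule, dense, cfg.k_ref, cfg.ph_ref)
        interps: dict = {}

        def _interp(key):
            if key not in interps:
                interps[key] = PchipInterpolator(dense, table[key])
            return interps[key]

        def _pos(vals, grid, step):
            p = np.clip((vals - grid[0]) / step, 0, len(grid) - 1 - 1e-9)
            idx = p.astype(int)
            return idx, p - idx

        q, fs = _pos(s_v, s_grid, _PROTEIN_STEP)
        r, fp = _pos(ph_v, ph_grid, _PH_STEP)
        u, ft = _pos(t1_v, t1_grid, t1_step)
        x_eval = offsets[None, :] - db0_v[:, None]
        zv = np.zeros((ph_v.size, offsets.size))
        for qq, rr, uu in {(int(a), int(b), int(c)) for a, b, c in zip(q, r, u)}:
            sel = (q == qq) & (r == rr) & (u == uu)
            xs = x_eval[sel]
            flat = xs.ravel()
            ws, wp, wt = fs[sel, None], fp[sel, None], ft[sel, None]
            # trilinear blend of the 8 surrounding table nodes
            for ds_ in (0, 1):
                for dp in (0, 1):
                    for dt in (0, 1):
                        w = ((ws if ds_ else 1 - ws)
                             * (wp if dp else 1 - wp)
                             * (wt if dt else 1 - wt))
                        corner = _interp((qq + ds_, rr + dp, uu + dt))
                        zv[sel] += w * corner(flat).reshape(xs.shape)
        z4d[vox] = np.clip(zv, 0.0, 1.0)

    m0 = np.zeros(shape)
    for lab, val in cfg.m0.items():
        m0[labels == lab] = val
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        z4d = z4d + rng.normal(0.0, noise_sd, size=z4d.shape)
    raw = z4d * m0[..., None]
    return raw, m0


def render_t1(phantom: DigitalPhantom, mode: str = "map",
              noise_sd: float = 0.0, seed: int = 0):
    """Quantitative T1 map or a two-flip-angle SPGR magnitude pair.

    ``mode="map"`` returns per-voxel T1 in seconds (class value plus
    optional Gaussian noise); ``mode="vfa"`` returns two ideally spoiled
    GRE volumes at the protocol's 4/24 degrees, TR 16.4 ms.
    """
    if mode not in ("map", "vfa"):
        raise ValueError(f"mode must be 'map' or 'vfa', got {mode!r}")
    cfg = phantom.config
    labels = phantom.label_volume
    t1 = phantom.t1_volume.copy()
    rng = np.random.default_rng(seed)
    if mode == "map":
        if noise_sd > 0:
            t1 = np.where(labels != BACKGROUND,
                          t1 + rng.normal(0.0, noise_sd, t1.shape), t1)
        return t1
    m0 = np.zeros(labels.shape)
    for lab, val in cfg.m0.items():
        m0[labels == lab] = val
    brain = labels != BACKGROUND
    t1_safe = np.where(brain, t1, 1.0)
    s1 = np.where(brain, spgr_signal(m0, t1_safe, PROTOCOL_VFA.fa1, PROTOCOL_VFA.tr), 0.0)
    s2 = np.where(brain, spgr_signal(m0, t1_safe, PROTOCOL_VFA.fa2, PROTOCOL_VFA.tr), 0.0)
    if noise_sd > 0:
        s1 = s1 + rng.normal(0.0, noise_sd, s1.shape)
        s2 = s2 + rng.normal(0.0, noise_sd, s2.shape)
    return s1, s2


def render_ph31p(phantom: DigitalPhantom, coarse_voxel=(30.0, 30.0, 25.0),
                 psf_mode: str = "gaussian", spectral: bool = False,
                 snr: float = 50.0, seed: int = 0):
    """Coarse 31P pH map from the phantom's ground truth.

    Default path: PSF-weighted average of the truth pH over each coarse
    voxel footprint ("box" = volume-weighted mean; "gaussian" = FWHM equal
    to the coarse pitch, emulating zero-filled-CSI leakage).  With
    ``spectral=True`` each coarse voxel instead synthesizes a 31P spectrum
    at the PSF-weighted Pi shift, fits the two-line model and converts the
    fitted distance back to pH — exercising the full measurement chain.

    Coarse voxels without brain support are dropped from the mask.
    Returns ``(ph31p, coarse_mask)``.
    """
    for c, f in zip(coarse_voxel, phantom.voxel_size):
        if c < f:
            raise ValueError("coarse voxel must be >= fine voxel per dimension")
    mask = phantom.analysis_mask()
    cal = HhCalibration()
    if not spectral:
        return psf_downsample(phantom.ph_volume, mask, phantom.voxel_size,
                              coarse_voxel, psf_mode)
    shift = np.where(mask, ph_to_shift(np.where(mask, phantom.ph_volume, 7.0), cal),
                     np.nan)
    shift_lo, cmask = psf_downsample(shift, mask, phantom.voxel_size,
                                     coarse_voxel, psf_mode)
    ph_lo = np.full(shift_lo.shape, np.nan)
    rng = np.random.default_rng(seed)
    for idx in zip(*np.nonzero(cmask)):
        ph_true = hh_ph(float(shift_lo[idx]), cal)
        spec = synthesize_spectrum(ph_true, snr=snr,
                                   seed=int(rng.integers(2 ** 31)), cal=cal)
        dist, _ = fit_pi_pcr_distance(spec)
        ph_lo[idx] = hh_ph(dist, cal)
    return ph_lo, cmask


def erode_mask(mask: np.ndarray, iterations: int = 1) -> np.ndarray:
    """Morphological erosion with a 6-connected structuring element."""
    mask = np.asarray(mask, dtype=bool)
    if iterations == 0:
        return mask.copy()
    struct = generate_binary_structure(3, 1)
    return binary_erosion(mask, structure=struct, iterations=iterations)


def simulate_dataset(seed: int = 1, config: PhantomConfig | None = None,
                     schedule: OffsetSchedule | None = None,
                     noise_sd: float = 0.005, t1_mode: str = "map",
                     qt1_noise_sd: float = 0.05,
                     coarse_voxel=(30.0, 30.0, 25.0), psf_mode: str = "gaussian",
                     erode_iterations: int = 1) -> AcquiredDataset:
    """End-to-end synthesis of one aligned dataset; deterministic per seed.

    ``qt1_noise_sd`` (s) is the measurement noise of the quantitative T1
    map — a two-point VFA fit is never noise-free on a scanner.
    """
    cfg = config or PhantomConfig()
    schedule = schedule or protocol_3t_schedule()
    seeds = [int(s.generate_state(1)[0] % (2 ** 31))
             for s in np.random.SeedSequence(seed).spawn(4)]
    phantom = build_phantom(cfg, seed=seeds[0])
    raw, m0 = render_cest(phantom, schedule, noise_sd=noise_sd, seed=seeds[1])
    qt1 = render_t1(phantom, mode="map", noise_sd=qt1_noise_sd, seed=seeds[2])
    vfa = render_t1(phantom, mode="vfa", noise_sd=0.0, seed=seeds[2]) \
        if t1_mode == "vfa" else None
    ph31p, cmask = render_ph31p(phantom, coarse_voxel=coarse_voxel,
                                psf_mode=psf_mode, seed=seeds[3])
    mask = erode_mask(phantom.analysis_mask(), erode_iterations)
    return AcquiredDataset(
        cest_4d=raw, m0=m0, offsets=np.asarray(schedule.offsets), qt1=qt1,
        vfa_pair=vfa, db0=phantom.db0_volume, ph31p=ph31p, ph31p_mask=cmask,
        coarse_voxel=tuple(coarse_voxel), mask=mask,
        truth_ph=phantom.ph_volume, voxel_size=phantom.voxel_size,
        seed=seed, config_hash=cfg.config_hash())
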