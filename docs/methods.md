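# Methods

This note documents the models implemented in `deepcestph`, the defaults
of the synthetic-data generator, the numerical choices, and the known
limitations — in particular, what the synthetic study does and does not
demonstrate about real scanner data.

## Z-spectrum forward model

Saturation transfer is propagated with the coupled Bloch–McConnell
equations for a water pool plus exchanging solute pools.  Each pool
carries a chemical shift (ppm from water), a proton fraction relative to
water, R1, R2, and an exchange rate to water; the reverse rate follows
from detailed balance (`k_water→pool = fraction · k_pool→water`).  The
default pool set is

| pool  | shift (ppm) | fraction | R2 (1/s) | k (1/s) | role |
|-------|------------:|---------:|---------:|--------:|------|
| water | 0           | 1        | tissue   | —       | observed signal |
| amide | +3.5        | 9·10⁻⁴   | 30       | k(pH)   | pH-sensitive APT effect |
| MT    | −2.4        | 0.01–0.07| 10⁵      | 40      | semi-solid background (broad-Lorentzian stand-in for the super-Lorentzian lineshape) |
| NOE   | −3.5        | 3·10⁻³   | 50       | 20      | relayed aliphatic effect |

MT and NOE are on by default so that MTR_asym has the realistic slightly
negative 3-T baseline instead of an artificially symmetric spectrum.

The saturation module is modelled literally: 10 rectangular startup
pulses plus one pulse per offset, duration t_p = 250 ms, gap
t_d = 250 ms, B1 = 1 μT.  Evolution is piecewise constant — one matrix
exponential of the (3N+1)-dimensional generator per pulse at the current
offset, free relaxation/exchange during gaps — and the Z value is the
longitudinal water magnetization after the final pulse, normalized by
equilibrium.  Constants: ω₁ = 2π · 42.577 · B1[μT] rad/s;
1 ppm = 2π · 42.577 · B₀[T] rad/s at B₀ = 3 T.

Two numerical notes:

- **Clipping.** Coherent nutation very close to water resonance can
  transiently leave M_z marginally negative; the idealized magnitude
  readout cannot report that, so Z is clipped to [0, 1].  Only
  |offset| ≲ 0.3 ppm is affected.
- **CW shortcut.** A continuous-wave approximation (one long pulse with
  duty-cycle-scaled B1) is available behind `cw_approx=True`.  It tracks
  the pulsed train only to ~0.05–0.1 in Z because it ignores inter-pulse
  transients; it is a quick-look tool, not the rendering path.

The simulator is validated against the closed-form single-pool
continuous-wave steady state `Z_ss = R1·cos²θ / (R1·cos²θ + R2·sin²θ)`,
`tanθ = ω₁/Δω`, which the propagator matches to ~10⁻⁵ relative in the
spin-lock regime.

### pH dependence

Amide proton exchange is base-catalyzed in the physiological range, so
the rate is modelled as one decade per pH unit:
`k(pH) = k_ref · 10^(pH − pH_ref)` with k_ref = 30 s⁻¹ at pH_ref = 7.0,
the order of magnitude of published amide rates.  Both constants are
configurable; no in-vivo calibration is claimed.  Supported pH range
6.0–8.0; outside it the law errors rather than extrapolates.

### Offset schedule

The 3-T protocol preset samples −8…+8 ppm at 0.5 ppm, densified to
0.1 ppm over ±(3…4) ppm.  That recipe yields **49 unique offsets**; the
protocol description we follow also quotes a 51-offset count that cannot
be reconstructed from the stated increments.  The schedule is fully
configurable; the preset keeps the 49 reconstructible offsets, making
the feature vector 49 + 11 + 1 = 61-dimensional.

## Digital phantom

The phantom is an ellipsoidal brain (default semi-axes 105 × 105 × 33 mm
on an 80 × 80 × 18 grid of 3 × 3 × 4 mm voxels) with a 3 mm outer CSF
shell, a 9 mm GM shell, a WM interior, and optionally a spherical tumor
(24 mm radius — glioblastoma scale — with a 10 mm necrotic core) in one
hemisphere.  Class defaults:

| class | pH | T1 (s) | T2 (s) | MT fraction | M0 |
|-------|-----:|-----:|-----:|----:|----:|
| WM           | 7.00 | 1.1 | 0.070 | 0.07 | 0.75 |
| GM           | 7.03 | 1.6 | 0.090 | 0.04 | 0.85 |
| CSF          | 7.10 | 4.3 | 2.0   | 0    | 1.00 |
| tumor rim    | 7.15 | 1.8 | 0.120 | 0.03 | 0.90 |
| necrotic core| 7.25 | 2.0 | 0.150 | 0.01 | 0.80 |

pH values sit inside the physiological 6.9–7.3 window with the tumor
elevated; T1/T2 are literature-typical 3-T values.  CSF is excluded from
the analysis mask (which is additionally eroded once, 6-connected).

Three smooth Gaussian-random-field heterogeneities make the phantom
behave like patient data rather than a lookup of its own labels:

- **pH field** — within-class sd 0.02 pH units, correlation length
  15 mm: smooth physiological variation.
- **Mobile-protein density** — scales the amide and NOE fractions
  (relative sd 0.10 in normal tissue, 0.35 in tumor, correlation length
  10 mm).  Protein concentration varies strongly in tumors, and
  fraction-sensitive metrics (MTR_asym, MTR_rex and especially AREX)
  inherit that variation; without this field AREX would be an
  unrealistically clean pH meter and the learning problem trivial.
- **T1 field** — within-class relative sd 0.05 (normal) / 0.15 (tumor),
  entering both the water R1 of the rendered spectra and the qT1 map.
  Tumor T1 is spatially heterogeneous in vivo (edema, infiltration);
  with a constant per-class T1 the qT1 channel would be a noiseless
  class code that no scanner produces, and a voxel-wise regressor would
  rationally lean on it — which would contradict the very robustness
  property the T1 attack probes.  The qT1 map additionally carries
  0.05 s of measurement noise (two-point VFA maps are noisy).

ΔB0 is a low-order random polynomial scaled to ±0.3 ppm over the brain
(zero-fill exact when the amplitude is configured to 0).  CEST noise is
Gaussian on the normalized Z scale, default sd 0.005; a Rician option is
deliberately omitted at typical CEST SNR.

### Fast rendering path

Rendering ~30 000 voxels × 49 offsets with per-voxel matrix exponentials
would be prohibitively slow, so `render_cest` evaluates each tissue
class on a lookup table over (protein scale × pH × T1) nodes
(steps 0.3 / 0.02 pH / half the class T1 range) at a dense 0.1-ppm
offset grid, then interpolates: monotone cubic (PCHIP) along offsets —
evaluated at `offset − ΔB0(voxel)` — and trilinear across the table
axes.  The fast path agrees with the exact propagator to < 2·10⁻³ in Z
(checked in the tests), below the default noise floor.

### ³¹P map and the partial-volume effect

The coarse ³¹P map is a PSF-weighted average of the ground-truth pH over
each 30 × 30 × 25 mm voxel.  `box` mode is the exact volume-overlap
average; the default `gaussian` mode uses a separable Gaussian with FWHM
equal to the coarse pitch, emulating the leakage of zero-filled CSI
without synthesizing k-space.  Coarse voxels with < 50 % in-mask weight
are dropped (the analogue of excluding skull-adjacent spectra).  An
optional spectral path synthesizes a two-Lorentzian ³¹P spectrum per
coarse voxel at the PSF-weighted Pi shift, fits it, and converts the
fitted distance — exercising the full measurement chain.  The same
weight machinery serves evaluation-side downsampling, so the two paths
agree bit-exactly.

## ³¹P spectroscopy model

pH follows from the Pi–PCr shift distance δ via the modified
Henderson–Hasselbalch equation
`pH = 6.77 + log₁₀((δ − 3.29)/(5.68 − δ))` (dihydrogen-phosphate pKa and
the protonated/deprotonated limiting shifts).  The conversion errors at
and beyond the limiting shifts instead of returning infinities, and is
clamped to pH 6.0–7.8.  The spectral fit is a frequency-domain
least-squares fit of two Lorentzians plus a constant baseline,
initialized at the two largest local maxima; a prior-knowledge
time-domain fit (AMARES-style) is intentionally not reproduced — only
the Pi–PCr distance feeds downstream.  At SNR 50 the full
synthesize→fit→convert chain is unbiased to < 0.005 pH units.

## CEST processing

- **Normalization**: Z = raw/M0; voxels with M0 below 10⁻⁹ of the
  maximum are masked, not divided.
- **B0 correction**: the value measured at nominal offset w belongs at
  w − ΔB0, so each voxel's spectrum is re-interpolated (PCHIP) at
  w + ΔB0; edge offsets take the nearest sample.  ΔB0 = 0 is a bit-exact
  identity.  Recovery of shifted spectra is interpolation-limited in the
  steep direct-water wings (|offset| < 2.5 ppm at B1 = 1 μT); in the
  exchange-weighted band it is accurate to < 10⁻³.
- **Metrics**: MTR_asym uses linear interpolation at ±Δω (immaterial at
  the 0.1-ppm sampling of the 3–4 ppm block); MTR_rex uses the
  opposite-side Z as its reference (asymmetry dialect — a
  Lorentzian-fit reference would be an alternative, not implemented);
  AREX = MTR_rex/T1.  A Z-floor of 0.05 masks spillover-dominated voxels
  for the 1/Z metrics, with the count reported.

## T1 mapping

Two-point VFA: y = S/sin α against x = S/tan α gives slope
E1 = exp(−TR/T1).  Per-voxel B1 scale multiplies both nominal flip
angles (4°/24°, TR 16.4 ms preset).  Voxels with slope outside (0, 1)
are masked, never returned as negative T1.  Ideal RF spoiling is assumed
on both the forward and inverse side; an insufficient-spoiling
correction is a documented non-feature, so absolute T1 accuracy claims
are limited to the ideal-SPGR world of the phantom.

## The probabilistic network

Architecture: input(61) → 10 → 20 → 10 ReLU trunk, then a linear mean
head and a variance head mapped positive by softplus plus a floor of
10⁻⁶ (an unconstrained variance head can go non-positive; the floor also
bounds the GNLL gradient).  Loss: Gaussian negative log-likelihood
`0.5·(log σ² + (y − μ)²/σ²)`, constant dropped.  Optimizer: Adam,
lr 0.001, batch 256, 1000 epochs, no early stopping by default
(best-validation checkpointing is opt-in).  The wider 64-128-256-512
architecture that overfits is reproducible via `NetConfig` but is not
the default.

The split is voxel-wise 80/20 at a fixed seed; standardization
statistics (per-dimension mean/sd for features, scalar mean/sd for the
target) are computed **on the training split only** and then frozen —
computing them on all rows would leak validation information.  qT1 is
standardized jointly as one more feature dimension.  Zero-variance
dimensions are pinned to sd 1 with a warning.

The network is implemented directly in numpy with explicit
backpropagation and a hand-written Adam.  At this size (~1000
parameters) that is faster than framework overhead, keeps the weights
bit-reproducible for a fixed seed (identical curves and weights across
runs, asserted in the tests), and makes the gradient checkable against
finite differences.

Training targets are the coarse ³¹P values resliced to the CEST grid
(each voxel takes the coarse value containing its center) — the same
presentation a resliced CSI map has on the imaging grid.

### What performance to expect, and why

On the default study (seed 1, 25 260 usable voxels) the held-out RMSE is
≈ 0.017 pH units and the 1σ coverage ≈ 0.66.  The held-out Pearson r is
≈ 0.6, and that is close to an information-theoretic ceiling rather than
an optimization failure: a gradient-boosted regressor reaches r ≈ 0.63
from the same noisy features, and even a regressor given the *noiseless*
ground-truth voxel state (pH, protein scale, T1, class) only reaches
r ≈ 0.73.  The residual variance of the target is neighborhood-driven —
the coarse ³¹P value mixes tissue around the voxel through the CSI PSF —
and is invisible to any purely voxel-wise feature set.  The package
therefore contracts r ≥ 0.5 on the default study; clinical-cohort
correlation figures are not meaningful anchors for this synthetic
setting.

## Evaluation

SSIM uses a Gaussian window (sd 1.5 voxels) with standard stabilization
constants (K1 = 0.01, K2 = 0.03) and a pooled symmetric dynamic range,
computed per axial slice and mask-averaged (3D windows behind a flag);
coarse grids smaller than the 11-voxel Gaussian window fall back to the
largest odd uniform window.  R² is reported as the squared Pearson r of
the scatter, not 1 − SS_res/SS_tot about the identity line.
Bland–Altman limits are mean ± 1.96·sd (n−1).  The metric ladder
downsamples every competing map to the ³¹P grid with the same PSF
machinery, z-normalizes over the shared coarse mask (making the ranking
invariant to affine rescaling) and ranks by |r|.

## Problem sizes

Defaults were chosen as the smallest sizes at which every contracted
property is comfortably exercised: 80 × 80 × 18 phantom grid
(≈ 29 000 eroded mask voxels, ≈ 25 000 usable training rows), 49-offset
schedule, 1000 training epochs; the examples use reduced grids and 300
epochs.  A full default study (simulate → process → train → evaluate)
takes about a minute on one CPU core.

## Limitations

- No anatomical template, motion, EPI distortion, coil profile, or
  Rician noise; passing tests show method correctness under the stated
  generative model, not robustness to real-scanner artifacts.
- The MT pool is a broad Lorentzian, not a super-Lorentzian; B1
  inhomogeneity of the saturation train is not modelled.
- The exchange-rate–pH law is an assumed one-decade-per-pH-unit
  base-catalyzed form; absolute pH accuracy on real data would require
  calibration.
- The ³¹P path emulates CSI blurring by PSF weighting only, without
  k-space synthesis, and the AMARES-style prior-knowledge fit is
  replaced by a plain two-Lorentzian least squares.
- Training and evaluation voxels come from the same phantom (the
  split is voxel-wise); generalization across subjects would need a
  multi-phantom protocol, for which per-phantom splitting is the
  supported option.
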