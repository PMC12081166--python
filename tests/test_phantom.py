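"""Digital phantom: geometry, determinism, rendering and PSF downsampling."""

from dataclasses import replace

import numpy as np
import pytest

from deepcestph import (OffsetSchedule, PROTOCOL_VFA, PhantomConfig, build_phantom,
                        erode_mask, render_cest, render_ph31p, render_t1,
                        simulate_dataset, vfa_fit)
from deepcestph.phantom import CSF, GM, TUMOR_RIM, WM
from deepcestph.resample import psf_downsample


class TestBuildPhantom:
    def test_deterministic_for_fixed_seed(self, small_phantom_config):
        a = build_phantom(small_phantom_config, seed=5)
        b = build_phantom(small_phantom_config, seed=5)
        assert np.array_equal(a.label_volume, b.label_volume)
        assert np.array_equal(a.ph_volume, b.ph_volume, equal_nan=True)
        assert np.array_equal(a.db0_volume, b.db0_volume)
        assert np.array_equal(a.t1_volume, b.t1_volume)

    def test_tumor_ph_elevated_over_wm(self, small_phantom_config):
        ph = build_phantom(small_phantom_config, seed=1)
        rim = ph.label_volume == TUMOR_RIM
        wm = ph.label_volume == WM
        assert rim.any() and wm.any()
        assert ph.ph_volume[rim].mean() > ph.ph_volume[wm].mean()

    def test_zero_amplitude_db0_is_exactly_zero(self, small_phantom_config):
        cfg = replace(small_phantom_config, db0_amplitude=0.0)
        ph = build_phantom(cfg, seed=1)
        assert np.all(ph.db0_volume == 0.0)

    def test_tumor_outside_brain_rejected(self, small_phantom_config):
        cfg = replace(small_phantom_config, tumor_center_offset=(60.0, 0.0, 0.0))
        with pytest.raises(ValueError):
            build_phantom(cfg, seed=1)

    def test_small_grid_rejected(self, small_phantom_config):
        cfg = replace(small_phantom_config, shape=(8, 24, 16))
        with pytest.raises(ValueError):
            build_phantom(cfg, seed=1)

    def test_default_geometry_has_enough_voxels(self):
        ph = build_phantom(PhantomConfig(), seed=1)
        assert erode_mask(ph.analysis_mask(), 1).sum() >= 20000


class TestRenderCest:
    def test_uniform_class_voxels_share_spectra(self, quiet_small_config):
        ph = build_phantom(quiet_small_config, seed=1)
        sched = OffsetSchedule(offsets=tuple(np.arange(-4, 4 + 1e-9, 0.5)))
        raw, m0 = render_cest(ph, sched, noise_sd=0.0, seed=0)
        wm = np.argwhere(ph.label_volume == WM)
        a, b = wm[0], wm[len(wm) // 2]
        assert np.allclose(raw[tuple(a)], raw[tuple(b)], atol=1e-12)

    def test_background_m0_zero_gives_zero_signal(self, quiet_small_config):
        ph = build_phantom(quiet_small_config, seed=1)
        sched = OffsetSchedule(offsets=(3.5, -3.5))
        raw, m0 = render_cest(ph, sched, noise_sd=0.0, seed=0)
        bg = ph.label_volume == 0
        assert np.all(raw[bg] == 0.0)
        assert np.all(m0[bg] == 0.0)

    def test_label_effect_increases_with_ph(self, quiet_small_config):
        ph = build_phantom(quiet_small_config, seed=1)
        sched = OffsetSchedule(offsets=(3.5,))
        wm = np.argwhere(ph.label_volume == WM)
        v1, v2 = tuple(wm[0]), tuple(wm[1])
        ph.ph_volume[v1] = 7.0
        ph.ph_volume[v2] = 7.2
        raw, m0 = render_cest(ph, sched, noise_sd=0.0, seed=0)
        z1 = raw[v1][0] / m0[v1]
        z2 = raw[v2][0] / m0[v2]
        assert (1 - z2) > (1 - z1)

    def test_deterministic_with_noise(self, quiet_small_config):
        ph = build_phantom(quiet_small_config, seed=1)
        sched = OffsetSchedule(offsets=(3.5, -3.5, 0.0))
        a, _ = render_cest(ph, sched, noise_sd=0.01, seed=9)
        b, _ = render_cest(ph, sched, noise_sd=0.01, seed=9)
        assert np.array_equal(a, b)

    def test_lookup_table_matches_exact_simulator(self, quiet_small_config):
        """Fast rendering path vs direct Bloch-McConnell propagation."""
        from deepcestph import TissueParams, zspectrum_with_b0_shift
        cfg = replace(quiet_small_config, db0_amplitude=0.2)
        ph = build_phantom(cfg, seed=3)
        sched = OffsetSchedule(offsets=tuple(np.arange(2.0, 4.5 + 1e-9, 0.25)))
        raw, m0 = render_cest(ph, sched, noise_sd=0.0, seed=0)
        wm = np.argwhere(ph.label_volume == WM)
        v = tuple(wm[7])
        tissue = ph.class_params[WM].with_ph(float(ph.ph_volume[v]))
        tissue = TissueParams(1.0 / float(ph.t1_volume[v]), tissue.water_R2,
                              tissue.pools, tissue.pH)
        z_exact = zspectrum_with_b0_shift(tissue, sched, float(ph.db0_volume[v]))
        z_fast = raw[v] / m0[v]
        assert np.max(np.abs(z_fast - z_exact)) < 2e-3


class TestRenderT1:
    def test_map_mode_equals_class_t1(self, quiet_small_config):
        ph = build_phantom(quiet_small_config, seed=1)
        qt1 = render_t1(ph, mode="map", noise_sd=0.0)
        assert np.allclose(qt1[ph.label_volume == WM], quiet_small_config.t1[WM])
        assert np.allclose(qt1[ph.label_volume == CSF], quiet_small_config.t1[CSF])

    def test_vfa_forward_inverse_roundtrip(self, quiet_small_config):
        ph = build_phantom(quiet_small_config, seed=1)
        s1, s2 = render_t1(ph, mode="vfa", noise_sd=0.0)
        t1_fit, _, ok = vfa_fit(s1, s2, PROTOCOL_VFA)
        brain = ph.label_volume != 0
        assert ok[brain].all()
        rel = np.abs(t1_fit[brain] - ph.t1_volume[brain]) / ph.t1_volume[brain]
        assert np.max(rel) < 1e-6

    def test_invalid_mode_rejected(self, quiet_small_config):
        ph = build_phantom(quiet_small_config, seed=1)
        with pytest.raises(ValueError):
            render_t1(ph, mode="banana")


class TestRenderPh31p:
    def test_uniform_ph_is_conserved(self, quiet_small_config):
        cfg = replace(quiet_small_config, ph={k: 7.0 for k in quiet_small_config.ph})
        ph = build_phantom(cfg, seed=1)
        lo, mask = render_ph31p(ph, coarse_voxel=(12.0, 12.0, 8.0), psf_mode="box")
        assert mask.any()
        assert np.allclose(lo[mask], 7.0, atol=1e-12)

    def test_box_mode_is_volume_weighted_mean(self):
        # half a at one side, half b: aligned 2x downsample -> (a+b)/2
        vals = np.zeros((4, 4, 4))
        vals[:2] = 7.0
        vals[2:] = 7.2
        mask = np.ones((4, 4, 4), bool)
        lo, lo_mask = psf_downsample(vals, mask, (1, 1, 1), (4, 4, 4), "box")
        assert lo[0, 0, 0] == pytest.approx(7.1, abs=1e-12)

    def test_gaussian_leaks_more_than_box(self):
        """On a sharp step the Gaussian PSF pulls the hot coarse voxel
        toward the surround more than the ideal box voxel does."""
        vals = np.full((12, 12, 4), 7.0)
        vals[4:8, 4:8, :] = 7.2  # hot blob exactly filling one coarse voxel
        mask = np.ones(vals.shape, bool)
        box, _ = psf_downsample(vals, mask, (1, 1, 1), (4, 4, 4), "box")
        gau, _ = psf_downsample(vals, mask, (1, 1, 1), (4, 4, 4), "gaussian")
        assert box[1, 1, 0] == pytest.approx(7.2, abs=1e-12)
        assert gau[1, 1, 0] < box[1, 1, 0]  # leakage from the 7.0 surround
        assert gau[0, 1, 0] > box[0, 1, 0]  # and into the neighbors

    def test_spectral_path_matches_direct(self, quiet_small_config):
        ph = build_phantom(quiet_small_config, seed=1)
        direct, m1 = render_ph31p(ph, coarse_voxel=(24.0, 24.0, 16.0),
                                  psf_mode="box")
        spectral, m2 = render_ph31p(ph, coarse_voxel=(24.0, 24.0, 16.0),
                                    psf_mode="box", spectral=True, snr=200, seed=4)
        assert np.array_equal(m1, m2)
        assert np.nanmax(np.abs(direct[m1] - spectral[m1])) < 0.01

    def test_coarse_voxel_smaller_than_fine_rejected(self, quiet_small_config):
        ph = build_phantom(quiet_small_config, seed=1)
        with pytest.raises(ValueError):
            render_ph31p(ph, coarse_voxel=(1.0, 30.0, 25.0))


class TestErodeMask:
    def test_block_erosion(self):
        m = np.zeros((7, 7, 7), bool)
        m[1:6, 1:6, 1:6] = True
        e = erode_mask(m, 1)
        expected = np.zeros_like(m)
        expected[2:5, 2:5, 2:5] = True
        assert np.array_equal(e, expected)

    def test_empty_mask_stays_empty(self):
        assert not erode_mask(np.zeros((5, 5, 5), bool), 1).any()

    def test_zero_iterations_is_identity(self):
        m = np.random.default_rng(0).random((6, 6, 6)) > 0.5
        assert np.array_equal(erode_mask(m, 0), m)


class TestDataset:
    def test_voxel_volume_ratio_is_625(self):
        cfg = PhantomConfig()
        coarse = (30.0, 30.0, 25.0)
        ratio = np.prod(coarse) / np.prod(cfg.voxel_size)
        assert ratio == 625.0

    def test_simulate_dataset_deterministic(self, small_phantom_config):
        sched = OffsetSchedule(offsets=(3.5, -3.5, 0.0))
        a = simulate_dataset(seed=3, config=small_phantom_config, schedule=sched)
        b = simulate_dataset(seed=3, config=small_phantom_config, schedule=sched)
        assert np.array_equal(a.cest_4d, b.cest_4d)
        assert np.array_equal(a.qt1, b.qt1)
        assert np.array_equal(a.ph31p, b.ph31p, equal_nan=True)

    def test_offset_count_consistency(self, small_phantom_config):
        sched = OffsetSchedule(offsets=(3.5, -3.5))
        ds = simulate_dataset(seed=1, config=small_phantom_config, schedule=sched)
        assert ds.cest_4d.shape[-1] == 2
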