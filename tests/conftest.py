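import numpy as np
import pytest

from deepcestph import (OffsetSchedule, PhantomConfig, Pool, TissueParams,
                        default_pools)


@pytest.fixture(scope="session")
def water_tissue():
    """Pure water, WM-like relaxation."""
    return TissueParams(water_R1=1 / 1.1, water_R2=1 / 0.07, pools=[], pH=7.0)


@pytest.fixture(scope="session")
def wm_tissue():
    return TissueParams(water_R1=1 / 1.1, water_R2=1 / 0.07,
                        pools=default_pools(), pH=7.0)


@pytest.fixture(scope="session")
def coarse_schedule():
    """Fast schedule: 0.5-ppm grid only, for unit tests."""
    return OffsetSchedule(offsets=tuple(np.arange(-8.0, 8.0 + 1e-9, 0.5)))


@pytest.fixture(scope="session")
def small_phantom_config():
    """A small brain for fast phantom tests (~2k masked voxels)."""
    return PhantomConfig(shape=(24, 24, 16), voxel_size=(3.0, 3.0, 4.0),
                         brain_semiaxes=(33.0, 33.0, 28.0),
                         csf_thickness=3.0, gm_thickness=7.0,
                         tumor_center_offset=(12.0, 0.0, 0.0),
                         tumor_radius=10.0, core_radius=4.0)


@pytest.fixture(scope="session")
def quiet_small_config(small_phantom_config):
    """Small phantom with all stochastic fields switched off."""
    from dataclasses import replace
    cfg = replace(small_phantom_config, ph_noise_sd=0.0, db0_amplitude=0.0)
    cfg.protein_rel_sd = {k: 0.0 for k in cfg.protein_rel_sd}
    cfg.t1_rel_sd = {k: 0.0 for k in cfg.t1_rel_sd}
    return cfg
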