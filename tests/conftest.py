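import numpy as np
import pytest

from crowntraits.simulate import default_config, simulate_forest


@pytest.fixture(scope="session")
def clean_scene():
    """Small noise-free scene with non-overlapping crowns.

    Noise-free in the spectral sense (spectral_noise_sd=0, no shadows) and
    geometrically clean (overlap=0) so trait recovery is exact for
    CHL/CAR/LWC/CH and the lidar traits are limited only by return counts.
    """
    cfg = default_config(n_crowns=60, seed=7, scene_extent=(110.0, 110.0),
                         overlap=0.0, points_per_m2=25.0)
    return simulate_forest(cfg)


@pytest.fixture(scope="session")
def retrieved(clean_scene):
    from crowntraits.retrieval import retrieve_traits
    table, spectra, log = retrieve_traits(clean_scene.cube,
                                          clean_scene.cloud,
                                          clean_scene.crowns)
    return table, spectra, log


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
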