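import numpy as np
import pytest

from nbprox.scene_sim import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def noisefree_cfg() -> SceneConfig:
    """Small noise-free single-nucleus scene used across imaging tests."""
    return SceneConfig(
        field_shape=(24, 96, 96),
        n_nuclei=1,
        nucleus_radii_um=((1.2, 1.6), (2.4, 3.2)),
        n_bodies_per_nucleus=3,
        n_foci_per_nucleus=2,
        placement_mode="csr",
        min_separation_um=1.8,
        shot_noise=False,
        background_level=0.0,
        read_noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def noisefree_scene(noisefree_cfg):
    return generate_scene(noisefree_cfg, seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
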