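import numpy as np
import pytest

from kiwispec import SceneConfig, generate_attributes, generate_scene, calibrate_reflectance


@pytest.fixture(scope="session")
def clean_scene():
    """One noiseless 4-fruit Vis/NIR scene with its reference table and truth."""
    cfg = SceneConfig(n_fruits=4, noise_sd=0.0, seed=11)
    table = generate_attributes(4, seed=11)
    raw, dark, white, truth = generate_scene(cfg, table)
    return cfg, table, raw, dark, white, truth


@pytest.fixture(scope="session")
def clean_cube(clean_scene):
    """Calibrated reflectance cube of the noiseless scene."""
    _, _, raw, dark, white, _ = clean_scene
    return calibrate_reflectance(raw, dark, white)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
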