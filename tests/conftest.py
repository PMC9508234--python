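import warnings

import numpy as np
import pytest
from hypothesis import settings

from grasstrend import SceneConfig, generate_scene

warnings.filterwarnings("ignore", message="Mean of empty slice")

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_scene():
    """A 24x24x20 default-condition scene shared by read-only tests."""
    cfg = SceneConfig(n_rows=24, n_cols=24, seed=11)
    ndvi, climate, truth = generate_scene(cfg)
    return cfg, ndvi, climate, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
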