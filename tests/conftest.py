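import numpy as np
import pytest

from ovimyo.morphometry import MorphometryConfig
from ovimyo.synthetic import FiberMosaicSpec, make_fiber_mosaic


@pytest.fixture(scope="session")
def noiseless_mosaic():
    """50-fiber noiseless boundary-stained mosaic with ground truth."""
    spec = FiberMosaicSpec(
        n_fibers=50, mean_area_px=5000, area_cv=0.15, noise_sd=0.0, seed=42
    )
    image, label_map, areas = make_fiber_mosaic(spec)
    return spec, image, label_map, areas


@pytest.fixture()
def default_config():
    return MorphometryConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
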