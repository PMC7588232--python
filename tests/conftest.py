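import numpy as np
import pytest

from forcebind.io_formats import RunConfig
from forcebind.synth_fixtures import default_filament_specs, synth_movie


@pytest.fixture(scope="session")
def config():
    return RunConfig()


@pytest.fixture(scope="session")
def seeded_movie():
    """Default-SNR synthetic movie with three well-separated filaments."""
    specs = default_filament_specs((0.5, 1.5, 2.5), seed=1)
    actin, abp, truth = synth_movie(specs, shape=(192, 192), n_frames=15, seed=1)
    return actin, abp, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
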