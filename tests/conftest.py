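import numpy as np
import pytest

from ki67tma import CoreSpec, generate_core, universal_config


@pytest.fixture(scope="session")
def config():
    return universal_config()


@pytest.fixture(scope="session")
def clean_core():
    """One clean 100-nucleus core at the default calibration, with truth."""
    spec = CoreSpec(core_id="fixture", n_nuclei=100, positive_fraction=0.2, seed=2)
    image, truth = generate_core(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def dense_core():
    """A denser core for pixel-level and CAV checks."""
    spec = CoreSpec(core_id="dense", n_nuclei=300, positive_fraction=0.3, seed=5)
    image, truth = generate_core(spec)
    return spec, image, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
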