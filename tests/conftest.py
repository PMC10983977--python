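import numpy as np
import pytest

from smaddseq import PoreModel, SimConfig, build_pore_model


@pytest.fixture(scope="session")
def pore() -> PoreModel:
    return build_pore_model(seed=11)


@pytest.fixture()
def quiet_config() -> SimConfig:
    """Noise-free, fixed-dwell configuration for exact-value checks."""
    return SimConfig(seed=3, noise_sd=0.0, dwell_dispersion=0.0,
                     samples_per_base=9.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
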