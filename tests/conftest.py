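import numpy as np
import pytest

from toothtap import (
    ClassifierConfig,
    GenerationConfig,
    ImpulseSpec,
    SimConfig,
    ToothLayerParams,
    generate_dataset,
)


@pytest.fixture(scope="session")
def baseline_params() -> ToothLayerParams:
    return ToothLayerParams()


@pytest.fixture(scope="session")
def impulse() -> ImpulseSpec:
    return ImpulseSpec()


@pytest.fixture(scope="session")
def sim_cfg() -> SimConfig:
    return SimConfig()


@pytest.fixture(scope="session")
def small_bundle():
    """Reduced-scale baseline dataset (60/class, in memory) for quick checks."""
    return generate_dataset(GenerationConfig(n_per_class=60, master_seed=7))


@pytest.fixture(scope="session")
def medium_bundle():
    """100-per-class baseline draw used for feature-space separability checks."""
    return generate_dataset(GenerationConfig(n_per_class=100, master_seed=13))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_clf() -> ClassifierConfig:
    return ClassifierConfig()
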