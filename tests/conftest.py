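import numpy as np
import pytest

from gelrelax import ExperimentConfig, MaxwellElement, SyntheticGelSpec


@pytest.fixture
def cfg() -> ExperimentConfig:
    return ExperimentConfig()


@pytest.fixture
def two_element_gel() -> SyntheticGelSpec:
    """The reference recovery case: decade-separated fast and slow elements."""
    return SyntheticGelSpec(
        elements=[MaxwellElement(1.2, 0.5), MaxwellElement(0.6, 20.0)],
        noise_sigma=0.0,
        seed=42,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)
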