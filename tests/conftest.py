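import numpy as np
import pytest

from necrostoich.synthetic_data import GeneratorConfig, generate


@pytest.fixture(scope="session")
def noiseless_records():
    """One synthetic experiment with noise switched off (deterministic)."""
    return generate(GeneratorConfig(noise_cv=0.0, seed=0))


@pytest.fixture(scope="session")
def noisy_records():
    """One synthetic experiment at the default noise level."""
    return generate(GeneratorConfig(noise_cv=0.1, seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
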