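import numpy as np
import pytest

from dmnpipe import generate_phantom


@pytest.fixture(scope="session")
def clean_phantom():
    """Artifact-free phantom (network + drift + noise, no spikes/motion art)."""
    return generate_phantom("clean", seed=11)


@pytest.fixture(scope="session")
def patient_phantom():
    """Heavy-motion, spiked, enlarged-ventricle phantom."""
    return generate_phantom("patient", seed=7)


@pytest.fixture(scope="session")
def spikey_phantom():
    """Phantom with exactly five large spike volumes."""
    return generate_phantom("spikey", seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
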