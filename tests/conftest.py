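import numpy as np
import pytest

from eegsr.montage import build_standard_montage
from eegsr.synthetic import SyntheticConfig, generate_synthetic_dataset


@pytest.fixture(scope="session")
def montage64():
    return build_standard_montage(64)


@pytest.fixture(scope="session")
def montage16():
    return build_standard_montage(16)


@pytest.fixture(scope="session")
def small_dataset(montage16):
    """Desk-scale synthetic dataset: 16 channels, 32 Hz, 2-s windows."""
    cfg = SyntheticConfig(n_channels=16, rate=32.0, duration=2.0,
                          n_windows=24, n_classes=2, seed=7, montage=montage16)
    return generate_synthetic_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
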