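import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from ivimtex.models import default_scheme  # noqa: E402
from ivimtex.phantom import PhantomConfig, make_phantom  # noqa: E402


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_noisy_phantom():
    """16x16x8 phantom at SNR 20, shared by fitting tests."""
    return make_phantom(PhantomConfig(shape=(16, 16, 8),
                                      lesion_radii=(4, 4, 2.5),
                                      snr_b0=20.0, seed=3))


@pytest.fixture(scope="session")
def noiseless_phantom():
    return make_phantom(PhantomConfig(shape=(8, 8, 3),
                                      lesion_radii=(2.5, 2.5, 1.2),
                                      organ_radii=(3.8, 3.8, 1.5),
                                      snr_b0=np.inf, seed=7))
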