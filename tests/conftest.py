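import numpy as np
import pytest

from nmrqsar.binning import make_scheme


@pytest.fixture(scope="session")
def scheme_h():
    """0.1-ppm proton scheme (120 bins, origin 0.0019)."""
    return make_scheme("1H", 0.1)


@pytest.fixture(scope="session")
def scheme_c():
    """0.5-ppm carbon scheme (400 bins, origin -0.0073)."""
    return make_scheme("13C", 0.5)


@pytest.fixture(scope="session")
def blob_data():
    """Two well-separated Gaussian blobs (sigma 0.1, centers 10 apart)."""
    rng = np.random.default_rng(1)
    X = np.vstack(
        [rng.normal(0.0, 0.1, size=(50, 5)), rng.normal(10.0, 0.1, size=(50, 5))]
    )
    labels = np.array([0] * 50 + [1] * 50)
    return X, labels
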