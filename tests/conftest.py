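import numpy as np
import pytest

from elina import preprocess
from elina.synthetic import default_fixture


@pytest.fixture(scope="session")
def campaign():
    """The documented synthetic campaign (fixed seed)."""
    return default_fixture()


@pytest.fixture(scope="session")
def bucket_table(campaign):
    """Full-range 0.0005-ppm bucket table of the fixture series."""
    return preprocess.bucket(campaign.series, 0.5, 7.0, 0.0005)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
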