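import numpy as np
import pytest

from arealnet.netio import build_fixtures


@pytest.fixture(scope="session")
def fixtures():
    return build_fixtures(seed=20100916)


@pytest.fixture(scope="session")
def hyp(fixtures):
    """The experimentally hypothesised network document."""
    return fixtures.hypothesised_network


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20100916)


@pytest.fixture(scope="session")
def random_masks_200(fixtures):
    return fixtures.random_masks(200)
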