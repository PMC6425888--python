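import numpy as np
import pytest

from dendroprov import synthetic


@pytest.fixture(scope="session")
def fixture_suite():
    """One canned three-scenario bundle shared by the whole session."""
    return synthetic.make_fixture_suite(seed=7)


@pytest.fixture(scope="session")
def dry_climate():
    return synthetic.simulate_site_climate(
        synthetic.default_sites()["DRY"], years=50, seed=11)


@pytest.fixture(scope="session")
def moist_climate():
    return synthetic.simulate_site_climate(
        synthetic.default_sites()["MOIST"], years=50, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
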