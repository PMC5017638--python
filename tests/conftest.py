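import numpy as np
import pytest

import netstim as ns


@pytest.fixture(scope="session")
def small_connectome():
    """A 20-region default-profile connectome, fixed seed."""
    net, regions = ns.generate_connectome(n_regions=20, seed=7)
    return net, regions


@pytest.fixture(scope="session")
def default_connectome():
    """A full-size (83-region) default connectome, fixed seed."""
    net, regions = ns.generate_connectome(n_regions=83, seed=0)
    return net, regions


@pytest.fixture()
def params_deterministic():
    """Standard model constants with noise switched off."""
    return ns.WCParams(sigma=0.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
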