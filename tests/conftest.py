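import numpy as np
import pytest

from optoca1 import cable, light, morphology, pipeline


@pytest.fixture(scope="session")
def small_pyr():
    """Reduced synthetic pyramidal cell (coarse segments, shallow trees)."""
    return pipeline.build_cell("pyramidal", seed=1, max_seg_len=40.0,
                               scale="small")


@pytest.fixture(scope="session")
def small_basket():
    return pipeline.build_cell("basket", seed=1, max_seg_len=40.0,
                               scale="small")


@pytest.fixture(scope="session")
def membrane():
    return cable.MembraneModel()


@pytest.fixture(scope="session")
def gray_field():
    """Desk-scale gray-matter fluence field (shared across tests)."""
    return light.run_monte_carlo(dr=0.01, dz=0.01, n_photons=100_000, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
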