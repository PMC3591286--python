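import numpy as np
import pytest

from traplinesim import ModelParams, regular_polygon


@pytest.fixture(scope="session")
def pentagon():
    """Five flowers on a regular pentagon (5 m sides), nest at the centroid."""
    return regular_polygon(5, 5.0, nest_at="centroid")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def default_params():
    return ModelParams(enhancement_factor=2.0, n_bouts=65, rng_seed=0)
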