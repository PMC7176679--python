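"""Shared fixtures: seeded synthetic datasets at the default study scale."""

import pytest

from villizon import synthetic, scrna
from villizon.types import PipelineThresholds


@pytest.fixture(scope="session")
def thresholds():
    return PipelineThresholds()


@pytest.fixture(scope="session")
def params():
    return synthetic.GeneratorParams()


@pytest.fixture(scope="session")
def truth0(params):
    return synthetic.make_truth(params, seed=0)


@pytest.fixture(scope="session")
def reference0(truth0, params):
    return synthetic.gen_epithelial_reference(truth0, params, seed=0)


@pytest.fixture(scope="session")
def lcm0(truth0, reference0, params):
    return synthetic.gen_lcm_samples(truth0, reference0, params, seed=0)


@pytest.fixture(scope="session")
def umis0(truth0, params):
    return synthetic.gen_plate_umis(truth0, params, seed=0)


@pytest.fixture(scope="session")
def scrna0(umis0, thresholds):
    """Full single-cell processing of the seed-0 synthetic plates."""
    return scrna.run_scrna(umis0, thresholds, seed=0)
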