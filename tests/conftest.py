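import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from starprofile import (
    DEFAULT_LIBRARY_DEPTHS,
    build_program,
    generate_reference,
    sample_counts,
)
from starprofile.simulate import SimConfig

SMALL_DEPTHS = {k: v // 100 for k, v in DEFAULT_LIBRARY_DEPTHS.items()}


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_genes=60, seed=11, library_depths=dict(SMALL_DEPTHS))


@pytest.fixture(scope="session")
def small_reference(small_config):
    return generate_reference(small_config.n_genes, (300, 600), seed=11)


@pytest.fixture(scope="session")
def small_programs(small_config):
    return build_program(small_config)


@pytest.fixture(scope="session")
def small_counts(small_programs, small_config):
    return sample_counts(small_programs, small_config.library_depths, seed=12)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
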