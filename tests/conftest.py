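import logging

import numpy as np
import pytest

from capsidpcr import SimulationConfig, generate_community, simulate_reads

logging.getLogger("capsidpcr").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_model():
    """A small deterministic community: 2k reads/layer, noisy reads."""
    cfg = SimulationConfig(seed=7, reads_per_layer=2000)
    return generate_community(cfg)


@pytest.fixture(scope="session")
def small_reads(small_model):
    return simulate_reads(small_model)


@pytest.fixture(scope="session")
def clean_model():
    """Error-free community at modest depth for exact-recovery checks."""
    cfg = SimulationConfig(seed=11, reads_per_layer=5000, error_rate=0.0)
    return generate_community(cfg)


@pytest.fixture(scope="session")
def clean_reads(clean_model):
    return simulate_reads(clean_model)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
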