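import numpy as np
import pytest

from wormcpg.body import BodyGeometry
from wormcpg.config import load_body_constants, load_ranges
from wormcpg.simulation import SimConfig, run_embodied


@pytest.fixture(scope="session")
def ranges():
    return load_ranges()


@pytest.fixture(scope="session")
def constants():
    return load_body_constants()


@pytest.fixture(scope="session")
def geometry(constants):
    return BodyGeometry.from_constants(constants)


@pytest.fixture(scope="session")
def oscillator_genotype():
    from wormcpg.fixtures import demo_oscillator_genotype

    return demo_oscillator_genotype()


@pytest.fixture(scope="session")
def locomotor_genotype():
    from wormcpg.fixtures import demo_locomotor_genotype

    return demo_locomotor_genotype()


@pytest.fixture(scope="session")
def analysis_config():
    """Shortened protocol for embodied analysis tests (~7 cycles retained)."""
    return SimConfig(duration=20.0, transient=4.0)


@pytest.fixture(scope="session")
def locomotor_trace(locomotor_genotype, analysis_config):
    """Baseline embodied run of the demo locomotor, shared across tests."""
    return run_embodied(locomotor_genotype, analysis_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
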