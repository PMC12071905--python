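import numpy as np
import pytest
from hypothesis import settings

from ormsim import default_fixture_scenario, run_design, score_table

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_config():
    return default_fixture_scenario(seed=0)


@pytest.fixture(scope="session")
def doe50(fixture_config):
    """Full crossed design at 50 replicates per cell; shared across tests."""
    import dataclasses
    cfg = dataclasses.replace(fixture_config, replicates=50)
    return cfg, run_design(cfg)


@pytest.fixture(scope="session")
def scored50(doe50):
    cfg, table = doe50
    scored, bounds = score_table(table)
    return cfg, scored, bounds


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
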