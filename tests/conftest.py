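import numpy as np
import pytest
from hypothesis import settings

from redoxpath.config import default_config
from redoxpath.analysis import calibrated_model
from redoxpath.synthetic import generate_fixture, reference_scenarios

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def model(config):
    m, _ = calibrated_model(config)
    return m


@pytest.fixture(scope="session")
def scenario_fixtures(tmp_path_factory):
    """All six canonical fixtures, generated once per test session."""
    out = tmp_path_factory.mktemp("fixtures")
    specs = reference_scenarios(seed=11)
    result = {}
    for name, spec in specs.items():
        path, manifest = generate_fixture(spec, out, name=name)
        result[name] = (spec, path, manifest)
    return result


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
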