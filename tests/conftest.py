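import numpy as np
import pytest

from rootprime import ScenarioConfig, make_fixture, preset
from rootprime.geometry import build_root_tissue, default_prepattern


@pytest.fixture()
def fixture_config() -> ScenarioConfig:
    """Miniature tissue configuration (45 x 200 points, quarter-scale zones)."""
    return preset("baseline", fixture_scale=True)


@pytest.fixture()
def fixture_tissue(fixture_config):
    return build_root_tissue(fixture_config.params.geometry)


@pytest.fixture()
def prepattern_table():
    return default_prepattern()


@pytest.fixture()
def rng():
    return np.random.default_rng(20220927)
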