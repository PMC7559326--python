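import numpy as np
import pytest

from surfilm.spr import default_stack
from surfilm.synthetic import gen_scenario_fixture, write_fixture


@pytest.fixture(scope="session")
def angle_grid():
    return np.arange(50.0, 77.5 + 1e-9, 0.01)


@pytest.fixture(scope="session")
def coarse_angle_grid():
    return np.arange(50.0, 77.5 + 1e-9, 0.05)


@pytest.fixture(scope="session")
def gold_stack():
    return default_stack(670.0)


@pytest.fixture(scope="session")
def fixture_bundle():
    return gen_scenario_fixture(seed=1)


@pytest.fixture(scope="session")
def fixture_dir(fixture_bundle, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("fixture")
    write_fixture(fixture_bundle, outdir)
    return outdir
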