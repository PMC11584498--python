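import warnings

import numpy as np
import pytest

from vasotone.fixtures import make_fixture
from vasotone.geometry import tag_calcification
from vasotone.mechanics import FEModel, InelasticState

warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def unit_fixture():
    """Coarse (24 x 5) annulus mesh and default config."""
    return make_fixture("unit")


@pytest.fixture(scope="session")
def unit_mesh(unit_fixture):
    return unit_fixture[0]


@pytest.fixture(scope="session")
def unit_config(unit_fixture):
    return unit_fixture[1]


@pytest.fixture(scope="session")
def calcified_mesh(unit_mesh):
    return tag_calcification(unit_mesh, angular_fraction=1.0 / 3.0)


@pytest.fixture(scope="session")
def unit_fe_model(unit_mesh, unit_config):
    return FEModel(unit_mesh, unit_config.materials())


@pytest.fixture(scope="session")
def basal_inelastic(unit_mesh, unit_config):
    tone = unit_config.tone
    lam_cs = 1.0 + tone.xi_c * (tone.lambda_b - 1.0)
    return InelasticState.uniform(unit_mesh, tone.lambda_b, lam_cs)


@pytest.fixture(scope="session")
def basal_solutions(unit_fe_model, basal_inelastic):
    """Basal-tone equilibria at 0 and 100 mmHg (session-cached)."""
    s0 = unit_fe_model.solve(0.0, basal_inelastic)
    s100 = unit_fe_model.solve(100.0, basal_inelastic, u0=s0.u, p0=0.0)
    return {0: s0, 100: s100}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240320)
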