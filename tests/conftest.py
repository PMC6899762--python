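import numpy as np
import pytest

from wedesign import (
    TargetProfile,
    TransformSpec,
    builtin_scenarios,
    combination_design,
    single_agent_design,
)


@pytest.fixture(scope="session")
def target():
    return TargetProfile(gamma_t=0.01, gamma_e=0.99)


@pytest.fixture(scope="session")
def scca_transform():
    return TransformSpec.from_anchors(psi=0.0, psi_prime=-4.5)


@pytest.fixture(scope="session")
def single_config():
    return single_agent_design()


@pytest.fixture(scope="session")
def combo_config():
    return combination_design()


@pytest.fixture(scope="session")
def scenarios():
    return builtin_scenarios()


@pytest.fixture()
def rng():
    return np.random.default_rng(20230923)
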