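import numpy as np
import pytest

from whipneck import build_model, simulate
from whipneck.dynamics import compile_model
from whipneck.synthref import lab_sled_motion


@pytest.fixture(scope="session")
def v1_model():
    return build_model("V1-initial", "baseline")


@pytest.fixture(scope="session")
def v5b_model():
    return build_model("V5B-final", "with_prismatic")


@pytest.fixture(scope="session")
def lab_motion():
    return lab_sled_motion(0.3)


@pytest.fixture(scope="session")
def v1_result(v1_model, lab_motion):
    return simulate(v1_model, lab_motion, 0.3)


@pytest.fixture(scope="session")
def v5b_result(v5b_model, lab_motion):
    return simulate(v5b_model, lab_motion, 0.3)


@pytest.fixture(scope="session")
def two_body_model():
    from oracles import make_two_body_model
    return make_two_body_model()


@pytest.fixture(scope="session")
def two_body_compiled(two_body_model):
    return compile_model(two_body_model)


@pytest.fixture(scope="session")
def dp_oracle(two_body_model):
    from oracles import DoublePendulumOracle
    return DoublePendulumOracle(two_body_model)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
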