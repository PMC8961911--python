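import numpy as np
import pytest

from onoffseq import ModelSpec, Params

# the two nearly indistinguishable two-phase parameter vectors used
# throughout: theta1 = (q_on, q_off, l1, l2) = (0.1, 0.1, 1, 2) and
# theta2 = (0.1, 0.2, 2, 1); both give E[T] = 2.5 and p = 10/11


@pytest.fixture(scope="session")
def theta1():
    return Params(q_on=0.1, q_off=0.1, lambdas=(1.0, 2.0), mu=0.0)


@pytest.fixture(scope="session")
def theta2():
    return Params(q_on=0.1, q_off=0.2, lambdas=(2.0, 1.0), mu=0.0)


@pytest.fixture(scope="session")
def spec2_pure_birth():
    return ModelSpec(L=2, fixed={"mu": 0.0})


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def random_params(rng, L, has_switch=True, mu_range=(0.0, 1.0)):
    """Random positive rates for property tests."""
    kw = {}
    if has_switch:
        kw = {"q_on": rng.uniform(0.05, 2.0), "q_off": rng.uniform(0.05, 2.0)}
    return Params(
        lambdas=tuple(rng.uniform(0.3, 3.0, L)),
        mu=rng.uniform(*mu_range),
        **kw,
    )
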