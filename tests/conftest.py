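import numpy as np
import pytest

from asnkin import asn_model


@pytest.fixture(scope="session")
def asn_net():
    return asn_model.build_asn_network()


@pytest.fixture(scope="session")
def taasn1():
    return asn_model.enzyme_profile("TaASN1")


@pytest.fixture(scope="session")
def taasn2():
    return asn_model.enzyme_profile("TaASN2")


@pytest.fixture(scope="session")
def taasn1_trajectory(asn_net, taasn1):
    """Default forward simulation of TaASN1, shared across read-only tests."""
    from asnkin import integrate

    state0 = asn_model.default_initial_state("TaASN1")
    return integrate(asn_net, taasn1.params.as_dict(), state0)


@pytest.fixture(scope="session")
def taasn2_trajectory(asn_net, taasn2):
    from asnkin import integrate

    state0 = asn_model.default_initial_state("TaASN2")
    return integrate(asn_net, taasn2.params.as_dict(), state0)


def random_states_and_params(n, seed=0):
    """Random nonnegative states (over SPECIES order) and positive params."""
    rng = np.random.default_rng(seed)
    states = rng.uniform(0.0, 10.0, size=(n, len(asn_model.SPECIES)))
    params = 10.0 ** rng.uniform(-3, 3, size=(n, 5))
    return states, params
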