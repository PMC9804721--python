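import numpy as np
import pytest

from thermoniche import ChemostatParams, ConsumerParams, ResourceTraits


@pytest.fixture(scope="session")
def box1():
    """Printed consumer parameterisation (efficient consumer, R_0=0.5)."""
    return ConsumerParams(delta=0.5, m_a=0.01, m_b=0.1, m_c=0.05,
                          T_I=25.0, beta=150.0, R_0=0.5)


@pytest.fixture(scope="session")
def box1_r1(box1):
    from dataclasses import replace
    return replace(box1, R_0=1.0)


@pytest.fixture(scope="session")
def box1_r2(box1):
    from dataclasses import replace
    return replace(box1, R_0=2.0)


@pytest.fixture(scope="session")
def chemostat():
    return ChemostatParams(S=1.0, D=1.0)


@pytest.fixture(scope="session")
def resource():
    """Calibrated default resource traits (gamma = 0.525, no mismatch)."""
    return ResourceTraits()


@pytest.fixture(scope="session")
def T_grid():
    return np.arange(0.0, 40.0 + 0.025, 0.05)
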