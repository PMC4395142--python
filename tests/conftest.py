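import numpy as np
import pytest

from skyarm import ArmParameters, GainSet, OscillationSpec


@pytest.fixture(scope="session")
def params() -> ArmParameters:
    return ArmParameters.default()


@pytest.fixture(scope="session")
def gains() -> GainSet:
    return GainSet()


@pytest.fixture(scope="session")
def osc() -> OscillationSpec:
    return OscillationSpec()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20150413)


@pytest.fixture(scope="session")
def lagrangian_oracle():
    from _lagrangian_oracle import build_oracle

    return build_oracle()
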