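import numpy as np
import pytest

from cartimetrics import phantom as ph


@pytest.fixture(scope="session")
def default_spec() -> ph.PhantomSpec:
    return ph.PhantomSpec(seed=7)


@pytest.fixture(scope="session")
def default_model(default_spec) -> ph.TissueModel:
    return ph.build_phantom(default_spec)


@pytest.fixture(scope="session")
def predefect_model(default_spec) -> ph.TissueModel:
    return ph.build_phantom(default_spec.without_defects())


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
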