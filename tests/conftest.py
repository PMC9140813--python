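import numpy as np
import pytest

import carcinofis as cf


@pytest.fixture(scope="session")
def system() -> cf.FuzzySystem:
    """The shipped default diagnostic system (expensive enough to share)."""
    return cf.default_system()


@pytest.fixture(scope="session")
def worked_example() -> dict:
    """Crisp inputs of the published single-patient walk-through."""
    return dict(cf.WORKED_EXAMPLE)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20220521)
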