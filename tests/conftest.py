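import numpy as np
import pytest

from boldfish import GameParams, PersonalityState, build_default_success_table


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def params():
    """Canonical settings: six agents, b=2, c=1, λ=0.9."""
    return GameParams()


@pytest.fixture
def default_table():
    return build_default_success_table(6)


@pytest.fixture
def state6(rng):
    return PersonalityState(rng.uniform(0.05, 0.95, 6))
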