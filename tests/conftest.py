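import numpy as np
import pytest

import respgate as rg


@pytest.fixture(scope="session")
def phantom_signal() -> rg.RespiratorySignal:
    """Perfectly regular 20 s breathing trace (667 points at 0.03 s)."""
    return rg.generate(rg.preset("phantom"))


@pytest.fixture(scope="session")
def regular_signal() -> rg.RespiratorySignal:
    """Quasi-periodic volunteer-like trace with mild jitter and noise."""
    return rg.generate(rg.preset("volunteer_regular", seed=1))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
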