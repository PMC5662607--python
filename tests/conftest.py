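import numpy as np
import pytest

from boutlangevin import ModelParams


@pytest.fixture
def unit_params() -> ModelParams:
    """Reference parameter set: unit acceleration variance, cue rate and drag
    (zeta = 1, eta = 1)."""
    return ModelParams(nu_a2=1.0, omega=1.0, gamma=1.0)


@pytest.fixture
def fig_zeta_grid() -> list[float]:
    """The drag grid spanning the three regimes: zeta = 4**n, n = -3..3."""
    return [4.0**n for n in range(-3, 4)]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)
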