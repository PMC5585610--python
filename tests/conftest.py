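import numpy as np
import pytest

from dctherapy import ModelParams, default_x0


@pytest.fixture(scope="session")
def params() -> ModelParams:
    return ModelParams()


@pytest.fixture()
def x0() -> np.ndarray:
    return default_x0()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20170820)


def random_states(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random physiological states spanning the model's magnitude range."""
    T = 10.0 ** rng.uniform(2, 11, n)
    H = rng.uniform(0.0, 1.0, n)
    C = rng.uniform(0.0, 1.0, n)
    D = 10.0 ** rng.uniform(0, 6, n)
    I = 10.0 ** rng.uniform(0, 5, n)
    Fb = 10.0 ** rng.uniform(0, 4, n)
    Fg = 10.0 ** rng.uniform(-6, -3, n)
    Mi = rng.uniform(50.0, 250.0, n)
    return np.column_stack([T, H, C, D, I, Fb, Fg, Mi])
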