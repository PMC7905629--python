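import numpy as np
import pandas as pd
import pytest

from telemark.discretize import build_grid
from telemark.simulate import default_registry


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def study_grid():
    """The full 24-month weekly grid with four seasons."""
    return build_grid()


@pytest.fixture
def small_grid():
    """A short two-season grid for fast tests."""
    return build_grid(
        start="2017-04-01",
        end="2017-08-31",
        season_starts=[("S1", "2017-04-01"), ("S2", "2017-06-01")],
    )


def ts(s: str) -> pd.Timestamp:
    return pd.Timestamp(s, tz="UTC")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
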