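import numpy as np
import pytest

from lifeyears import LifeTable, SimConfig, make_life_table


@pytest.fixture
def toy_table() -> LifeTable:
    """Open 4-age table with interval death probabilities [0, .1, .2, .3]."""
    return LifeTable.from_columns(
        [0, 1, 2, 3], qx=[0.0, 0.1, 0.2, 0.3], radix=100_000, close=False
    )


@pytest.fixture
def weibull_table() -> LifeTable:
    """Noiseless table from a Weibull hazard (b=1/80, shape 7)."""
    return make_life_table(SimConfig(hazard="weibull", params={"b": 1 / 80, "l": 7.0}))


@pytest.fixture
def gm_table() -> LifeTable:
    """Noiseless table from the default Gompertz-Makeham schedule."""
    return make_life_table(SimConfig())


@pytest.fixture
def constant_table() -> LifeTable:
    """Open constant-probability table: qx = 0.3 at every age 0..60."""
    return LifeTable.from_columns(
        np.arange(61), qx=np.full(61, 0.3), radix=100_000, close=False
    )
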