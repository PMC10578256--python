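import numpy as np
import pytest

from orbitq.epg import build_dictionary


@pytest.fixture(scope="session")
def dictionary():
    """Full default dictionary (101 x 51 water, 17 x 51 fat atoms)."""
    return build_dictionary()


@pytest.fixture(scope="session")
def small_dictionary():
    """Coarse dictionary for fast unit tests."""
    return build_dictionary(
        t2water_grid_ms=np.arange(10.0, 60.5, 2.5),
        t2fat_grid_ms=np.arange(120.0, 201.0, 20.0),
        b1_grid=np.arange(0.5, 1.001, 0.05),
    )
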