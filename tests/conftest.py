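import numpy as np
import pytest

from hdsemg3d.grid_io import ElectrodeGrid, Recording, capgmyo_grid


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_grid():
    return ElectrodeGrid(2, 3, layout_name="tiny")


@pytest.fixture
def random_recording(rng):
    grid = capgmyo_grid()
    return Recording(
        signal=rng.standard_normal((grid.n_channels, 1000)),
        fs=1000.0,
        grid=grid,
        meta={"subject": 1, "gesture": 3, "trial": 0},
    )
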