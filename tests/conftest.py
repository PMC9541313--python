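import numpy as np
import pytest

from prothallus.render import RenderParams, render
from prothallus.simulate import SimParams, simulate


@pytest.fixture(scope="session")
def sheet_series():
    """A small meristem sheet grown for three windows (session-cached)."""
    return simulate(
        SimParams(n_windows=3, rng_seed=1, initial_sheet=(4, 10, 22, 16))
    )


@pytest.fixture(scope="session")
def rendered_snapshot(sheet_series):
    """Default-noise render of the final snapshot plus its ground truth."""
    cells = sheet_series.snapshot_cells(-1)
    img, truth, l2c = render(cells, RenderParams(rng_seed=1))
    return img, truth, l2c, cells


@pytest.fixture(scope="session")
def noiseless_snapshot(sheet_series):
    cells = sheet_series.snapshot_cells(-1)
    img, truth, l2c = render(
        cells, RenderParams(noise_sd=0.0, blur_sigma=0.0, rng_seed=1)
    )
    return img, truth, l2c, cells


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
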