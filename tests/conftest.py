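import numpy as np
import pytest

from geobiodiv.raster import RasterGrid


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def small_grid():
    """5x4 grid with distinct values, origin at (0, 150), 30 m cells."""
    vals = np.arange(20, dtype=float).reshape(5, 4)
    return RasterGrid(values=vals, origin=(0.0, 150.0), cell_size=30.0)


def orthogonal_predictors(n: int, seed: int, sd: float = 1.0):
    """Three exactly decorrelated predictors with unit-ish spread."""
    rng = np.random.default_rng(seed)
    M = rng.standard_normal((n, 3))
    M -= M.mean(axis=0)
    Q, _ = np.linalg.qr(M)
    cols = Q / Q.std(axis=0) * sd
    return cols[:, 0], cols[:, 1], cols[:, 2]
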