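import numpy as np
import pytest

from boldcsf.io import MaskVolume, QcPolicy, Volume4D
from boldcsf.preproc import TimeSeries
from boldcsf.simulate import SyntheticConfig


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_volume(rng):
    """16x16x8 grid, 40 volumes, TR 2 s."""
    data = rng.normal(size=(16, 16, 8, 40))
    return Volume4D(data=data, voxel_size=(3.5, 3.5, 3.5), tr=2.0)


@pytest.fixture
def gm_mask(small_volume):
    m = np.zeros(small_volume.spatial_shape, dtype=bool)
    m[4:12, 4:12, 3:7] = True
    return MaskVolume(m, small_volume.voxel_size)


@pytest.fixture
def csf_mask(small_volume):
    m = np.zeros(small_volume.spatial_shape, dtype=bool)
    m[6:10, 6:10, 0] = True
    return MaskVolume(m, small_volume.voxel_size)


@pytest.fixture
def policy():
    return QcPolicy()


@pytest.fixture
def tiny_config():
    """Fast generator config for unit tests."""
    return SyntheticConfig(n_bqd=3, n_hc=3, n_volumes=120, seed=7)


def make_series(values, dt=2.0):
    return TimeSeries(values=np.asarray(values, dtype=float), dt=dt)


def naive_lagged_pearson(g, c, k):
    """Independent shift-slice-correlate oracle for one lag (samples)."""
    n = min(len(g), len(c))
    g, c = np.asarray(g)[:n], np.asarray(c)[:n]
    if k >= 0:
        x, y = g[k:], c[: n - k]
    else:
        x, y = g[: n + k], c[-k:]
    return np.corrcoef(x, y)[0, 1]
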