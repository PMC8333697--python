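import numpy as np
import pytest

from netdc.images import BoldSeries, default_affine


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_series(data, tr=2.0, spacing=3.0):
    """Wrap a 4D array as a BoldSeries with a centered isotropic affine."""
    data = np.asarray(data, dtype=float)
    return BoldSeries(data=data, affine=default_affine(spacing, data.shape[:3]),
                      tr=tr)


def series_from_matrix(matrix, tr=2.0):
    """Build a (V, 1, 1, T) series from a (V, T) matrix of voxel time courses."""
    matrix = np.asarray(matrix, dtype=float)
    return make_series(matrix[:, None, None, :], tr=tr)


@pytest.fixture
def toy_series(rng):
    """Random 30-voxel, 40-frame series on a (30,1,1) grid with a full mask."""
    data = rng.standard_normal((30, 40))
    series = series_from_matrix(data)
    mask = np.ones((30, 1, 1), dtype=bool)
    return series, mask
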