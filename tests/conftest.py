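import numpy as np
import pytest

from landmosaic import LandCoverRaster


@pytest.fixture
def rng():
    return np.random.default_rng(20240529)


def brute_force_counts(grid: np.ndarray, side: int) -> np.ndarray:
    """Literal per-pixel window counting: the engine's independent oracle.

    Returns a (4, rows, cols) array of per-class counts of the centred
    side x side window intersected with the grid (class 0 = nodata count).
    """
    r = side // 2
    rows, cols = grid.shape
    out = np.zeros((4, rows, cols), dtype=np.int64)
    for i in range(rows):
        for j in range(cols):
            win = grid[max(i - r, 0): i + r + 1, max(j - r, 0): j + r + 1]
            for c in range(4):
                out[c, i, j] = int((win == c).sum())
    return out


@pytest.fixture
def two_patch_raster():
    """Left half agriculture, right half natural: pure patches at small
    windows, interface at large ones."""
    g = np.full((120, 120), 2, dtype=np.uint8)
    g[:, :60] = 1
    return LandCoverRaster(g)
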