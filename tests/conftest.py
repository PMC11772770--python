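import numpy as np
import pytest

from tipland.grids import Raster


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cover(rng):
    """Random 66x66 ten-class cover raster at 30 m with a little nodata."""
    values = rng.integers(0, 10, size=(66, 66)).astype(np.int16)
    values[0, :3] = -1
    return Raster(values, cell_size=30.0, nodata=-1)


def naive_block_counts(values, valid, window, r0, c0):
    """Brute-force per-class tally of one block (oracle for upscaling)."""
    counts = {}
    for r in range(r0, min(r0 + window, values.shape[0])):
        for c in range(c0, min(c0 + window, values.shape[1])):
            if valid[r, c]:
                counts[values[r, c]] = counts.get(values[r, c], 0) + 1
    return counts
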