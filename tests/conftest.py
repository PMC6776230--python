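import numpy as np
import pytest

from plaqueomics.io import VoxelLesion


def make_random_lesion(rng, shape=(4, 4, 3), density=0.7, hu_range=(-50, 200),
                       lesion_id="test"):
    """Small random lesion on a dense grid subset, for oracle comparisons."""
    grid = np.argwhere(np.ones(shape, dtype=bool))
    n = max(2, int(density * len(grid)))
    idx = rng.choice(len(grid), size=n, replace=False)
    coords = grid[np.sort(idx)]
    values = rng.integers(hu_range[0], hu_range[1], size=n)
    return VoxelLesion(values=values, coords=coords,
                       spacing_mm=(0.4, 0.4, 0.6), lesion_id=lesion_id)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def random_lesion(rng):
    return make_random_lesion(rng)
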