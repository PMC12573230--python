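import numpy as np
import pytest

from imsrpca import IMSMatrix, gen_synthetic_ims


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_matrix(rng):
    """10 pixels x 5 peaks with random non-negative intensities."""
    vals = rng.uniform(0, 10, size=(10, 5))
    coords = np.stack(
        [np.tile(np.arange(5), 2), np.repeat(np.arange(2), 5)], axis=1
    )
    return IMSMatrix(
        values=vals,
        pixel_coords=coords,
        mz_axis=np.linspace(400, 800, 5),
        meta={"unit": "counts"},
    )


@pytest.fixture(scope="session")
def ims_cube():
    """Default synthetic IMS-like datacube with known ground truth."""
    return gen_synthetic_ims(seed=0)
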