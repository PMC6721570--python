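import numpy as np
import pytest

from radiosurv.volume import ImageVolume, QuantizedROI, ROIMask


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_quantized_roi(rng, shape=(8, 8, 8), ng=6, mask_prob=0.7):
    """A random quantized ROI with an irregular mask."""
    mask = rng.random(shape) < mask_prob
    if not mask.any():
        mask[tuple(s // 2 for s in shape)] = True
    levels = np.zeros(shape, dtype=np.int32)
    levels[mask] = rng.integers(1, ng + 1, size=int(mask.sum()))
    return QuantizedROI(levels, ng, mask)


@pytest.fixture
def roi_factory(rng):
    return lambda **kw: random_quantized_roi(rng, **kw)


@pytest.fixture
def small_lesion():
    from radiosurv.synthetic import generate_lesion

    return generate_lesion((32, 32, 32), (1.0, 1.0, 1.0), 9.0, 3.0, seed=4)


def single_slice_roi(rows, ng):
    """Build a 1-slice 3D quantized ROI from a 2D nested list (0 = outside)."""
    arr = np.asarray(rows, dtype=np.int32)[None, :, :]
    return QuantizedROI(arr, ng, arr > 0)
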