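import numpy as np
import pytest

from usradiomics.imaging import QuantizedROI


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_roi(levels, mask=None, ng=None, role="tumor"):
    """Build a QuantizedROI directly from an integer level array."""
    levels = np.asarray(levels, dtype=np.int64)
    if mask is None:
        mask = np.ones(levels.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if ng is None:
        ng = max(4, 1 << int(np.ceil(np.log2(levels[mask].max() + 1))) if levels[mask].max() > 0 else 4)
    lv = np.where(mask, levels, -1)
    return QuantizedROI(lv, mask, ng, role, constant=bool(np.ptp(levels[mask]) == 0))


@pytest.fixture
def roi_factory():
    return make_roi


def random_roi(rng, max_side=8, ng=8):
    """Random small quantized ROI with a random (non-empty) mask."""
    h = int(rng.integers(2, max_side + 1))
    w = int(rng.integers(2, max_side + 1))
    levels = rng.integers(0, ng, size=(h, w))
    mask = rng.random((h, w)) < 0.8
    if not mask.any():
        mask[rng.integers(h), rng.integers(w)] = True
    return make_roi(levels, mask, ng=ng)
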