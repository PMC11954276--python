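import numpy as np
import pytest

from hipporad.fmri_derivatives import Bold4D


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_bold(rng):
    """Random finite 6x6x6x64 BOLD volume, full brain mask, TR = 2 s."""
    data = rng.normal(size=(6, 6, 6, 64))
    return Bold4D(data, tr_seconds=2.0)


@pytest.fixture
def random_levels(rng):
    """A 5^3 discretized ROI with 4 gray levels and a few out-of-ROI voxels."""
    from hipporad.radiomics_features import DiscretizedRoi

    lev = rng.integers(1, 5, size=(5, 5, 5))
    lev[0, 0, 0] = 0
    lev[4, 4, 4] = 0
    return DiscretizedRoi(levels=lev, n_levels=4)
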