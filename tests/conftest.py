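import numpy as np
import pytest

from sparsect.geometry import Geometry


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_geom():
    """32x32 grid, 16 views over 180 degrees."""
    return Geometry(n_views=16, n_bins=32, image_size=32)
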