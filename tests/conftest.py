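import numpy as np
import pytest

from adipoquant import ImagePlane, SimParams, generate_field


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_params(**overrides) -> SimParams:
    """Compact field for unit tests: 512 px, 30 cells, defaults otherwise."""
    base = dict(shape=(512, 512), n_cells=30, seed=42)
    base.update(overrides)
    return SimParams(**base)


@pytest.fixture(scope="session")
def small_field():
    """One generated 512-px field shared by read-only tests."""
    p = SimParams(shape=(512, 512), n_cells=30, seed=42)
    return p, generate_field(p)


def plane(arr, bit_depth=16, pixel_size=0.31) -> ImagePlane:
    return ImagePlane(np.asarray(arr, dtype=float), bit_depth, pixel_size)
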