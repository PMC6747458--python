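import numpy as np
import pytest

from gliaquant.types import Field, FieldGeometry


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_geometry():
    """Coarse desk-scale geometry: full 0.1502 mm² field on 256² pixels."""
    return FieldGeometry(n_pixels=256)


@pytest.fixture
def fine_geometry():
    """Finer sampling for morphometry checks."""
    return FieldGeometry(n_pixels=512)


def zero_field(n: int = 128, pixel_size: float = 0.5, **kw) -> Field:
    return Field(np.zeros((n, n)), pixel_size, **kw)


@pytest.fixture
def make_zero_field():
    return zero_field
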