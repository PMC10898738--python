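import numpy as np
import pytest

from tenodesis_fe.synthetic_fixtures import PhantomSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom_spec():
    """Light phantom (small bones, same tunnel sizes) for fast end-to-end
    tests; the tunnel-resolution constraint still holds at edge 1 mm."""
    return PhantomSpec(femur_size=(16.0, 16.0, 16.0),
                       tibia_size=(16.0, 16.0, 16.0),
                       plateau_width=16.0, edge_length=1.0)
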