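import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def disk_phantom():
    """Clean 128x128 bright-disk phantom with ground truth."""
    from spfseg.phantoms import PhantomSpec, generate

    return generate(PhantomSpec())


@pytest.fixture
def small_image(rng):
    """Random 16x16 intensity field in [0, 1]."""
    return rng.random((16, 16))
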