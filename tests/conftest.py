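import numpy as np
import pytest

from fusionnet3d.phantom import PhantomSpec, generate


@pytest.fixture(scope="session")
def desk_phantom():
    """One fixed 32-voxel phantom with all four modalities."""
    return generate(PhantomSpec(edge=32, seed=7))


@pytest.fixture(scope="session")
def tiny_phantom():
    """A 16-voxel phantom for fast training smoke tests."""
    return generate(PhantomSpec(edge=16, seed=3, center_jitter=1.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
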