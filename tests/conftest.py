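import numpy as np
import pytest

from gtvseg.synthetic import PhantomSpec, generate_phantom
from gtvseg.volumes_io import LabelMask, Volume


@pytest.fixture(scope="session")
def phantom():
    """One default phantom (volume, mask) pair reused across read-only tests."""
    return generate_phantom(PhantomSpec(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def small_volume():
    data = np.random.default_rng(0).normal(10.0, 2.0, size=(24, 20, 12)).astype(np.float32)
    return Volume(data, spacing=(1.0, 1.5, 3.0))


@pytest.fixture()
def sphere_mask():
    """A solid sphere labeled GTVp on a (64, 64, 32) anisotropic grid."""
    shape = (64, 64, 32)
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    r2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, (32, 32, 16), (12, 12, 6)))
    return LabelMask((r2 <= 1).astype(np.uint8), spacing=(1.0, 1.0, 2.0))
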