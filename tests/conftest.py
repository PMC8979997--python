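import numpy as np
import pytest

from cryoembed import (estimate_orientations, make_phantom, project_stack,
                       sample_uniform_orientations)
from cryoembed.simulate import ImageStack


@pytest.fixture(scope="session")
def phantom64():
    return make_phantom(64, seed=1)


@pytest.fixture(scope="session")
def noiseless_stack(phantom64):
    """30 noiseless projections of the desk phantom with ground truth."""
    orientations = sample_uniform_orientations(30, seed=2)
    data = project_stack(phantom64, orientations)
    return ImageStack(data, phantom64.voxel_size, orientations)


@pytest.fixture(scope="session")
def noiseless_outcome(noiseless_stack):
    """Full orientation estimation on the noiseless desk stack."""
    return estimate_orientations(noiseless_stack.data, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
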