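import numpy as np
import pytest

from annealct import (
    PhantomSpec,
    ProjectionGeometry,
    generate_lung_phantom,
    radon_forward,
)


@pytest.fixture(scope="session")
def phantom8():
    return generate_lung_phantom(PhantomSpec(side=8, seed=7))


@pytest.fixture(scope="session")
def phantom16():
    return generate_lung_phantom(PhantomSpec(side=16, seed=7))


@pytest.fixture(scope="session")
def geom8():
    return ProjectionGeometry.uniform(18, side=8)


@pytest.fixture(scope="session")
def sino8(phantom8, geom8):
    return radon_forward(phantom8, geom8)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
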