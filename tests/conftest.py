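import numpy as np
import pytest

from retfuse.synthetic import (
    DEFAULT_FUNDUS_SHAPE,
    PhantomSpec,
    generate_fundus_phantom,
    generate_oct_phantom,
)


@pytest.fixture(scope="session")
def me_oct_phantom():
    """An ME OCT phantom with two fluid blobs and its truth (seed 5)."""
    return generate_oct_phantom(PhantomSpec(label="me", seed=5, n_fluid_blobs=2))


@pytest.fixture(scope="session")
def healthy_oct_phantom():
    return generate_oct_phantom(PhantomSpec(label="healthy", seed=4))


@pytest.fixture(scope="session")
def me_fundus_phantom():
    """An ME fundus phantom (seed 13) with exudates near the macula."""
    return generate_fundus_phantom(
        PhantomSpec(shape=DEFAULT_FUNDUS_SHAPE, label="me", seed=13)
    )


@pytest.fixture(scope="session")
def healthy_fundus_phantom():
    return generate_fundus_phantom(
        PhantomSpec(shape=DEFAULT_FUNDUS_SHAPE, label="healthy", seed=9)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
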