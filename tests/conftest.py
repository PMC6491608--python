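import numpy as np
import pytest

from lobuseg import PhantomSpec, PreprocessParams, SegmentationParams, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """The reference phantom: 18 subunits, seed 42, default geometry."""
    return generate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def small_phantom():
    """A reduced phantom for fast end-to-end smoke tests."""
    spec = PhantomSpec(
        shape=(72, 72, 24),
        n_subunits=6,
        core_fraction=0.35,
        rng_seed=7,
        include_node_occluder=False,
    )
    return generate_phantom(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def default_pre():
    return PreprocessParams()


@pytest.fixture
def default_seg():
    return SegmentationParams()
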