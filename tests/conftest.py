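import numpy as np
import pytest

from rrlsrn import PhantomSpec, generate_dataset, generate_phantom

try:
    from hypothesis import settings

    settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def default_phantom():
    """One textured 128x128 phantom with sharp edges."""
    return generate_phantom(PhantomSpec(), seed=3)


@pytest.fixture(scope="session")
def smooth_phantom():
    """A heavily smoothed, texture-free phantom (low-frequency content only)."""
    spec = PhantomSpec(texture_amplitude=0.0, edge_smoothing_sigma=4.0)
    return generate_phantom(spec, seed=5)


@pytest.fixture(scope="session")
def phantom_batch():
    """Ten small phantoms for dataset-level tests."""
    return generate_dataset(10, PhantomSpec(height=64, width=64, n_ellipses=3), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
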