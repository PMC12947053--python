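import numpy as np
import pytest

from sphereseg import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def phantom():
    """Default desk-scale phantom case (64x64x48, noise sd 0.05, seed 1)."""
    spec = PhantomSpec(seed=1)
    volume, labels, roi = generate_phantom(spec)
    return spec, volume, labels, roi


@pytest.fixture(scope="session")
def noiseless_phantom():
    spec = PhantomSpec(noise_sd=0.0, seed=0)
    volume, labels, roi = generate_phantom(spec)
    return spec, volume, labels, roi


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(autouse=True)
def _quiet_degenerate_warnings():
    """Single-member stacks etc. warn by design; keep test output clean."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield
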