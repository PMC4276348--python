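import numpy as np
import pytest

from ctstroke import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free 256 px phantom with a left lesion, for geometric checks."""
    spec = PhantomSpec(size=256, noise_sd=0.0, lesion_side="left", seed=1)
    ct, truth = generate_phantom(spec)
    return spec, ct, truth


@pytest.fixture(scope="session")
def noisy_phantom():
    """Study-condition phantom: noise sd 1.5 HU, left lesion of 27.5 mm^2."""
    spec = PhantomSpec(size=256, seed=7, lesion_side="left")
    ct, truth = generate_phantom(spec)
    return spec, ct, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
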