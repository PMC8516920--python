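import numpy as np
import pytest

from scectgen.phantom import PhantomSpec, generate_phantom_pair


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec(shape=(64, 64, 16), spacing=(4.0, 4.0, 8.0), seed=11)


@pytest.fixture(scope="session")
def small_pair(small_spec):
    return generate_phantom_pair(small_spec)


@pytest.fixture(scope="session")
def noiseless_pair():
    spec = PhantomSpec(shape=(64, 64, 16), spacing=(4.0, 4.0, 8.0),
                       noise_sd=0.0, seed=11)
    return generate_phantom_pair(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
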