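import numpy as np
import pytest

from hepavol.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """A compact noise-bearing phantom shared by read-only tests."""
    spec = PhantomSpec(shape=(16, 48, 48), liver_axes_mm=(28.0, 22.0, 26.0),
                       liver_center_mm=(36.0, 36.0, 33.0), seed=11)
    return generate_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
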