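import numpy as np
import pytest

from cartiseg.phantom import PhantomSpec, generate_phantom


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_phantom():
    """One deterministic small phantom shared across read-only tests."""
    return generate_phantom(PhantomSpec(volume_shape=(24, 48, 48), seed=42))


@pytest.fixture(scope="session")
def desk_phantom():
    """Default desk-scale phantom (used where geometry fidelity matters)."""
    return generate_phantom(PhantomSpec(seed=7))
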