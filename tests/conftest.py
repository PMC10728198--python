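import numpy as np
import pytest

import pace2 as p2


@pytest.fixture(scope="session")
def default_phantom():
    """The default seeded 256x256 chest phantom and its truth masks."""
    return p2.generate_phantom(p2.PhantomSpec(seed=42))


@pytest.fixture(scope="session")
def default_run(default_phantom):
    """One full pipeline run on the default phantom, shared across tests."""
    img, _ = default_phantom
    return img, p2.run_pace2(img)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
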