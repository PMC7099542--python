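import numpy as np
import pytest

import sinocad as sc


@pytest.fixture(scope="session")
def small_phantom():
    """One default phantom shared by segmentation/detection tests."""
    vol, truth = sc.generate_phantom(sc.PhantomConfig(seed=3))
    return vol, truth


@pytest.fixture(scope="session")
def small_patch_set():
    """A small labelled patch set shared across tests."""
    return sc.generate_patch_dataset(12, 12, patch_size=40, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
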