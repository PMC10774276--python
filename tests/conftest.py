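import numpy as np
import pytest

import selectivefd as sfd


@pytest.fixture(scope="session")
def blobs10():
    """Balanced 10-class, 8-d, well-separated blob dataset."""
    return sfd.make_blobs(C=10, per_class=100, d=8, separation=8, noise_sd=1, seed=7)


@pytest.fixture(scope="session")
def strong_partition(blobs10):
    """Strong non-IID split: 10 clients, one class each."""
    return sfd.partition_clients(blobs10, K=10, classes_per_client=1, seed=3)


@pytest.fixture(scope="session")
def base_config():
    return sfd.FederationConfig(
        K=10, C=10, T=8, label_mode="hard", proxy_batch=100, seed=1
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
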