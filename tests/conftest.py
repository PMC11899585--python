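import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_linear_dataset():
    """Small linear-generator dataset shared by CNN-level tests."""
    import medcnn

    cfg = medcnn.make_scenario(
        "alternative", n=200, network_sizes=(16, 12), seed=42
    )
    return medcnn.generate_dataset(cfg)
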