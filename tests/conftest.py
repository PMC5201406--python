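import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_params():
    """Small dense 2-state, 3-symbol model for hand-checkable cases."""
    from hmdm.hmm import HmmParameters

    return HmmParameters(
        pi=np.array([0.6, 0.4]),
        A=np.array([[0.7, 0.3], [0.4, 0.6]]),
        B=np.array([[0.5, 0.4, 0.1], [0.1, 0.3, 0.6]]),
    )


@pytest.fixture(scope="session")
def ground_truth():
    from hmdm.synthetic import default_ground_truth

    return default_ground_truth()
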