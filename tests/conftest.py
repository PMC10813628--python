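import numpy as np
import pytest

from benthomap.synthetic import CommunityRule, SeascapeConfig, generate_seascape


@pytest.fixture(scope="session")
def small_config():
    return SeascapeConfig(
        extent=10_000.0, cell_size=1000.0, seed=7, n_grab=80, n_video=30
    )


@pytest.fixture(scope="session")
def small_seascape(small_config):
    return generate_seascape(small_config)


@pytest.fixture(scope="session")
def default_rule():
    return CommunityRule.default()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
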