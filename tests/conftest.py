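import numpy as np
import pytest

from ctlearn.config import PipelineConfig, TargetConfig
from ctlearn.targets import make_repeated_segment


@pytest.fixture(scope="session")
def target_cfg():
    return TargetConfig()


@pytest.fixture(scope="session")
def repeated(target_cfg):
    return make_repeated_segment(target_cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def desk_cfg():
    return PipelineConfig.desk_scale(seed=7)
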