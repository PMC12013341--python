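import numpy as np
import pytest
from hypothesis import settings

from musemind import default_timeline

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def short_timeline():
    """Scaled-down session (1-min baseline, 2-min sections) for fast tests."""
    return default_timeline(baseline_dur=60.0, section_dur=120.0, inter_gap=10.0)


@pytest.fixture
def full_timeline():
    """Study-scale session: 4-min baseline, two 15-min sections."""
    return default_timeline()
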