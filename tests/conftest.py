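import numpy as np
import pytest

from axonedit.datasets import sqkv1a_assay_summary, sqkv1a_sites


@pytest.fixture
def assay_summary():
    return sqkv1a_assay_summary()


@pytest.fixture
def assay_sites():
    return sqkv1a_sites()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
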