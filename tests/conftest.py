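import numpy as np
import pytest

from dtialps import (
    ROIConfig,
    default_phantom_spec,
    make_tensor_phantom,
    single_shell_table,
)


@pytest.fixture(scope="session")
def phantom():
    """Default noiseless phantom: (tensor, labels, analytic truth)."""
    return make_tensor_phantom(default_phantom_spec())


@pytest.fixture(scope="session")
def gtab32():
    return single_shell_table(n_dirs=32, b=1500.0)


@pytest.fixture
def roi_cfg():
    return ROIConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
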