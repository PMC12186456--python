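import numpy as np
import pytest

from grazefit.simulate import default_plan


@pytest.fixture(scope="session")
def density_grid():
    """20 prey levels spanning the usual experimental range."""
    return np.geomspace(1_000.0, 70_000.0, 20)


@pytest.fixture(scope="session")
def reference_plan():
    return default_plan()
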