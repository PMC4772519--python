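import numpy as np
import pytest

from phagodyn import reference_parameters


@pytest.fixture(scope="session")
def ref_params():
    return reference_parameters()


@pytest.fixture(scope="session")
def halfhour_grid():
    """The 30-minute reporting grid over the 16-hour observation window."""
    return np.round(np.arange(0.0, 16.25, 0.5), 10)
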