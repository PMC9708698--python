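import numpy as np
import pytest

from iminoex.core_model import RelaxationRates
from iminoex.synthetic_data import default_hprna20_truth

#: the study's five delay times, ascending
FIVE_DELAYS = np.array([0.001, 0.01, 0.03, 0.06, 0.1])


@pytest.fixture
def rates():
    """Apparent relaxation rates of the worked fitting examples."""
    return RelaxationRates(R1a=2.0, R1w=0.4)


@pytest.fixture
def truth():
    """Default hairpin ground truth, fixed seed."""
    return default_hprna20_truth(seed=1234)
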