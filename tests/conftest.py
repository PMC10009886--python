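import numpy as np
import pytest

from hepdyn import default_parameters


@pytest.fixture(scope="session")
def p0():
    """Baseline dimensionless parameter set."""
    return default_parameters()


@pytest.fixture()
def rng():
    return np.random.default_rng(20231115)


def random_parameters(rng, scale=1.0):
    """A random admissible parameter set (positive, O(scale))."""
    from hepdyn.params import PARAM_NAMES, DimensionlessParameters
    vals = {k: float(rng.uniform(0.01, 2.0)) * scale for k in PARAM_NAMES}
    return DimensionlessParameters(**vals)
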