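import numpy as np
import pytest

from caskinetics.kinetics_model import AssayMix, RateParameters
from caskinetics.synthetic_data import table1_fixtures


@pytest.fixture(scope="session")
def table1():
    return table1_fixtures()


@pytest.fixture(scope="session")
def table1_by_name(table1):
    return {rec.name: rec for rec in table1}


@pytest.fixture(scope="session")
def reference_rates():
    """The modeling section's example rate set (k2 chosen; only k_ON,T and
    k_ON,B / k_OFF,B are reported)."""
    return RateParameters(k_on_t=1.8e4, k2=1.0e4, k_on_b=1.1e6, k_off_b=0.026)


@pytest.fixture(scope="session")
def standard_mix():
    return AssayMix()


@pytest.fixture(scope="session")
def background_mix():
    return AssayMix(background_0=200.0)


@pytest.fixture(scope="session")
def minute_grid():
    """1-min sampling over 16 h: 961 points."""
    return np.arange(0.0, 961.0)
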