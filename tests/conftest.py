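import numpy as np
import pytest

from dipolemm import build_dimer, build_monomer, default_parameters
from dipolemm.calibrate import calibrated_parameters


@pytest.fixture(scope="session")
def ff():
    """Uncalibrated (MM3-like starting) parameters."""
    return default_parameters()


@pytest.fixture(scope="session")
def ff_cal():
    """The shipped calibrated parameter set."""
    return calibrated_parameters()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture()
def co2_dimer(ff):
    sys_, _ = build_dimer(("CO2", "CO2"), "min", ff=ff)
    return sys_


@pytest.fixture()
def mea_monomer(ff):
    return build_monomer("MEA", "trans", ff=ff)
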