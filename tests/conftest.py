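import numpy as np
import pytest

from phosflex import hydrodynamics as hyd
from phosflex import spin_physics as sp
from phosflex.synthetic import ScenarioTruth, NoiseSpec


@pytest.fixture(scope="session")
def p31():
    return sp.nucleus("31P")


@pytest.fixture(scope="session")
def field():
    return sp.FieldSpec(B0=11.7)


@pytest.fixture(scope="session")
def carrier_mhz(p31, field):
    return sp.larmor_frequency(p31, field) / 1e6


@pytest.fixture(scope="session")
def visc_model():
    return hyd.ViscosityModel.default()


@pytest.fixture(scope="session")
def interactions():
    return sp.default_p31_interactions()


@pytest.fixture()
def truth():
    """Default scenario truth with the standard noise levels."""
    return ScenarioTruth(seed=11)


@pytest.fixture()
def quiet_truth():
    """Noiseless scenario truth for exact forward-model checks."""
    return ScenarioTruth(seed=11, noise=NoiseSpec(relaxation=0.0, zspectrum=0.0,
                                                  dosy=0.0, integrals=0.0,
                                                  viscometry=0.0))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
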