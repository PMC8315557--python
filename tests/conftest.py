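import numpy as np
import pytest

from mesopolar import meso_rates as mr
from mesopolar import scenarios
from mesopolar.model import GeometryConstants, build_polarity_model

# benchmark microscopic parameters: lambda*pi*rho^2/D_tot = 50
FIG2_KMICRO = 0.25
FIG2_RHO = 0.005
FIG2_D = 0.0025  # per molecule
FIG2_DTOT = 0.005


@pytest.fixture(scope="session")
def fig2_micro() -> mr.MicroParams:
    return mr.MicroParams(k_micro=FIG2_KMICRO, rho=FIG2_RHO, d_tot=FIG2_DTOT)


@pytest.fixture(scope="session")
def geometry() -> GeometryConstants:
    return GeometryConstants()


@pytest.fixture(scope="session")
def polarity_model():
    return build_polarity_model(500, 2.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def association_model_pair():
    """One A and one B molecule, benchmark kinetics."""
    return scenarios.association_model(1, 1)
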