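import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from ppipkpd import (
    ILAPRAZOLE_PD,
    ILAPRAZOLE_PK,
    IndividualPK,
    daily_regimen,
    generate_internal_study,
    individual_pd_parameters,
)


@pytest.fixture(scope="session")
def pk_typical():
    return IndividualPK(CLp=2.57, CLt=4.59, Vc=8.80, Vt=3.65)


@pytest.fixture(scope="session")
def pd_typical():
    return individual_pd_parameters(ILAPRAZOLE_PD)


@pytest.fixture(scope="session")
def regimen_20mg():
    return daily_regimen([20.0], "20 mg")


@pytest.fixture(scope="session")
def internal_study():
    """One noisy internal-study realisation shared by read-only tests."""
    return generate_internal_study(ILAPRAZOLE_PK, ILAPRAZOLE_PD, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
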