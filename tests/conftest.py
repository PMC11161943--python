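import numpy as np
import pytest

from obcmi import RiskFactorProfile, get_system


@pytest.fixture(scope="session")
def validated():
    return get_system("validated")


@pytest.fixture(scope="session")
def modified():
    return get_system("modified")


@pytest.fixture()
def baseline_profile():
    """A woman with no risk factors (age and BMI below all bands)."""
    return RiskFactorProfile(age_years=28, bmi=24.0)


def make_profile(**flags) -> RiskFactorProfile:
    flags.setdefault("age_years", 28)
    flags.setdefault("bmi", 24.0)
    return RiskFactorProfile(**flags)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240608)
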