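import numpy as np
import pytest

from petdes.cohort import PatientProfile
from petdes.config import ScenarioConfig


@pytest.fixture(scope="session")
def cfg() -> ScenarioConfig:
    return ScenarioConfig().validate()


@pytest.fixture
def fresh_cfg() -> ScenarioConfig:
    """A mutable config copy for tests that override parameters."""
    return ScenarioConfig().validate()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)


def make_profile(**overrides) -> PatientProfile:
    """A hand-built dementia AD patient with explicit covariates."""
    base = dict(
        id=0, phase0="dementia", true_cause="AD", latent_dementia_cause="AD",
        age0=82.0, male=False, race="white",
        ckd=False, cvd=False, diabetes=False, hypertension=False, stroke=False,
        psymed=False, living_with_caregiver=True,
        caregiver_age=79.0, caregiver_male=True,
        mmse0=21.9, npi0=16.3, adl0=29.7, iadl0=29.1,
    )
    base.update(overrides)
    return PatientProfile(**base)


@pytest.fixture
def ad_profile() -> PatientProfile:
    return make_profile()


@pytest.fixture
def predementia_profile() -> PatientProfile:
    return make_profile(phase0="predementia", true_cause="prodromalAD",
                        latent_dementia_cause="AD", age0=78.0,
                        mmse0=27.5, npi0=2.5, adl0=10.1, iadl0=10.1)
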