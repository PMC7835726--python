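import dataclasses

import pytest

from verticality.model import ParticipantParameters, StimulusCondition
from verticality.reference import MEDIAN_PARAMS


@pytest.fixture(scope="session")
def median_params() -> ParticipantParameters:
    """Cohort-median observer coefficients used as canonical inputs."""
    return MEDIAN_PARAMS


@pytest.fixture(scope="session")
def free_params(median_params) -> ParticipantParameters:
    """Median coefficients augmented with constant free weights."""
    return dataclasses.replace(median_params, omega_hisd=0.4, omega_bisd=0.99)


@pytest.fixture
def upright_ar36() -> StimulusCondition:
    return StimulusCondition(platform_tilt_deg=0.0, head_tilted=False,
                             ar_tilt_deg=36.0)
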