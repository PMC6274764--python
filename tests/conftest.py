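import pytest
from hypothesis import HealthCheck, settings

from arsq import (
    FREE_ARS,
    WavelengthGrid,
    component_eem,
    noiseless_sample_eem,
    solve_complex_amplitude,
)

settings.register_profile(
    "arsq",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
settings.load_profile("arsq")


@pytest.fixture(scope="session")
def grid():
    return WavelengthGrid.default()


@pytest.fixture(scope="session")
def solved_amplitudes():
    """Complex amplitudes realizing the study fold targets (noiseless)."""
    return {fold: solve_complex_amplitude(fold) for fold in (2.0, 2.7, 3.0, 3.5)}


@pytest.fixture(scope="session")
def control_eem():
    return noiseless_sample_eem(1.0, 0.0)


@pytest.fixture(scope="session")
def om7_eem(solved_amplitudes):
    return noiseless_sample_eem(1.0, solved_amplitudes[2.0])


@pytest.fixture(scope="session")
def om14_eem(solved_amplitudes):
    return noiseless_sample_eem(1.0, solved_amplitudes[3.0])


@pytest.fixture(scope="session")
def free_dye_eem():
    return component_eem(FREE_ARS)
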