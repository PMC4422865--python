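import numpy as np
import pytest

from adcpk import (
    DoseEvent,
    default_adc_parameters,
    default_dar_distribution,
    default_mmae_parameters,
    default_population_parameters,
)


@pytest.fixture(scope="session")
def adc():
    return default_adc_parameters()


@pytest.fixture(scope="session")
def mmae():
    return default_mmae_parameters()


@pytest.fixture(scope="session")
def dar_dist():
    return default_dar_distribution()


@pytest.fixture(scope="session")
def pop():
    return default_population_parameters()


@pytest.fixture(scope="session")
def single_dose_times():
    return np.array([0, 1 / 12, 4, 12, 24, 72, 168, 336, 504, 672, 840, 1008.0])


@pytest.fixture(scope="session")
def adc_dose_03():
    return DoseEvent(time=0.0, compound="conjugate", dose_level=0.3, body_weight=2.5)


@pytest.fixture(scope="session")
def adc_dose_3():
    return DoseEvent(time=0.0, compound="conjugate", dose_level=3.0, body_weight=2.5)


@pytest.fixture(scope="session")
def mmae_dose():
    return DoseEvent(time=0.0, compound="mmae", dose_level=0.03, body_weight=2.5)
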