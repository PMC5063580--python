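import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from outbreaksync.records import AnnualBinarySeries, ClimateSeries, StudyPeriod

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def period10():
    return StudyPeriod(1700, 1709)


@pytest.fixture
def period():
    return StudyPeriod(1700, 1990)


def make_binary(region_id, first_year, values):
    return AnnualBinarySeries(
        region_id=region_id, first_year=first_year, values=np.asarray(values)
    )


def make_climate(region_id, first_year, values):
    return ClimateSeries(
        region_id=region_id, first_year=first_year, values=np.asarray(values, dtype=float)
    )
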