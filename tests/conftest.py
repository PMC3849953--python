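import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from reachadapt.fixtures_io import load_fixture, load_segments
from reachadapt.trajectory import Point3, Segment

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def segments():
    """The 13 task segments with synthesised endpoints."""
    return load_segments()


@pytest.fixture(scope="session")
def segment_map(segments):
    return {s.id: s for s in segments}


@pytest.fixture(scope="session")
def table3():
    return load_fixture("table3_durations")


@pytest.fixture
def unit_segment():
    """A 1 m segment along the x axis, convenient for hand calculations."""
    return Segment(
        id=1,
        length=1.0,
        embedded=False,
        reach=True,
        gravity="ground",
        cross_body="large",
        source=Point3(0.0, 0.0, 0.0),
        target=Point3(1.0, 0.0, 0.0),
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
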