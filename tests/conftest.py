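import math

import numpy as np
import pytest

from spiderstat.cage_geometry import CordState, Subject
from spiderstat.cord_model import CordCharacteristic, CordSpec
from spiderstat.fixtures import reference_characteristic
from spiderstat.statics import GRAVITY, Stance


@pytest.fixture(scope="session")
def adult_thick() -> CordCharacteristic:
    return reference_characteristic("reference_adult_thick")


@pytest.fixture(scope="session")
def child_thin() -> CordCharacteristic:
    return reference_characteristic("reference_child_thin")


@pytest.fixture(scope="session")
def adult() -> Subject:
    return Subject(mass=75.0, height=1.75, cog_height=0.98)


@pytest.fixture(scope="session")
def child() -> Subject:
    return Subject(mass=12.0, height=0.88, cog_height=0.51)


@pytest.fixture
def single_term_char() -> CordCharacteristic:
    """Quarter-sine characteristic: T(x) = 10 sin(pi x / 200), T(100) = 10 N."""
    return CordCharacteristic(
        CordSpec("thick"),
        terms=((10.0, math.pi / 200.0, 0.0), (0.0, 0.01, 0.0), (0.0, 0.01, 0.0)),
    )


def make_state(direction, tension: float) -> CordState:
    """Build a CordState directly from a direction and a tension (tests only)."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    return CordState(
        direction=tuple(d),
        stretched_length=1.0,
        elongation_pct=50.0,
        cog_level_angle=math.degrees(math.asin(max(-1.0, min(1.0, d[2])))),
        tension=tension,
    )


def random_two_foot_scenario(rng: np.random.Generator):
    """A random subject, cord set and stance guaranteed short of lift-off."""
    mass = rng.uniform(12.0, 105.0)
    height = rng.uniform(0.8, 1.95)
    subject = Subject(mass=mass, height=height, cog_height=0.55 * height)
    n_cords = rng.integers(1, 7)
    weight = mass * GRAVITY
    states = []
    for _ in range(n_cords):
        v = rng.normal(size=3)
        while np.linalg.norm(v) < 1e-6:
            v = rng.normal(size=3)
        # cap tensions so the summed vertical pull stays below ~80% of weight
        states.append(make_state(v, rng.uniform(0.0, 0.8 * weight / n_cords)))
    stance = Stance(
        left=(rng.uniform(-0.15, 0.15), rng.uniform(0.05, 0.30)),
        right=(rng.uniform(-0.15, 0.15), rng.uniform(-0.30, -0.05)),
    )
    return subject, states, stance
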