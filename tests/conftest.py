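import numpy as np
import pytest

from bowlscreen.geometry import ProjectorModel
from bowlscreen.goldberg import build_goldberg, equalize_areas


@pytest.fixture(scope="session")
def model():
    return ProjectorModel()


@pytest.fixture(scope="session")
def goldberg_raw():
    return build_goldberg(3, 3)


@pytest.fixture(scope="session")
def goldberg_eq(goldberg_raw):
    return equalize_areas(goldberg_raw)


def intersect_lines(p1, d1, p2, d2):
    """Brute-force 2-line intersection oracle: solve the 2x2 linear system
    p1 + t*d1 = p2 + s*d2 for (t, s) and return the point."""
    a = np.stack([d1, -np.asarray(d2)], axis=1)
    t, _ = np.linalg.solve(a, np.asarray(p2) - np.asarray(p1))
    return np.asarray(p1) + t * np.asarray(d1)


@pytest.fixture(scope="session")
def line_oracle():
    return intersect_lines
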