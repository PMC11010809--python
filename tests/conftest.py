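import numpy as np
import pytest

from scalemorph import OutlinePolygon, make_template, species_templates


@pytest.fixture
def unit_square():
    return OutlinePolygon(np.array([[0.0, 0.0], [1, 0], [1, 1], [0, 1]]))


@pytest.fixture
def circle_poly():
    t = np.linspace(0, 2 * np.pi, 10_000, endpoint=False)
    return OutlinePolygon(np.column_stack((np.cos(t), np.sin(t))))


@pytest.fixture
def ellipse_poly():
    """x = 2 cos t, y = sin t sampled densely at equal parameter steps."""
    t = np.linspace(0, 2 * np.pi, 4000, endpoint=False)
    return OutlinePolygon(np.column_stack((2 * np.cos(t), np.sin(t))))


@pytest.fixture(scope="session")
def wavy_template():
    return make_template("waved")


@pytest.fixture(scope="session")
def five_templates():
    return species_templates()


def rotate(points, theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.asarray(points) @ np.array([[c, s], [-s, c]])
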