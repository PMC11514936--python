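import numpy as np
import pytest

from blebmorph import BlebOutline


def make_ellipse_polygon(a, b, theta_deg=0.0, center=(0.0, 0.0), n=256, phase=0.0):
    """Polygon sampling a rotated ellipse at n uniform parameter values."""
    t = phase + 2.0 * np.pi * np.arange(n) / n
    th = np.radians(theta_deg)
    bx, by = a * np.cos(t), b * np.sin(t)
    rot = np.column_stack(
        [np.cos(th) * bx - np.sin(th) * by, np.sin(th) * bx + np.cos(th) * by]
    )
    return BlebOutline(rot + np.asarray(center))


def star_polygon(rng, n=64, r_mean=3.0, wobble=0.5, center=(0.0, 0.0)):
    """Random simple star-shaped polygon around `center`."""
    phi = 2.0 * np.pi * np.arange(n) / n
    r = r_mean * (1.0 + wobble * (rng.random(n) - 0.5))
    verts = np.column_stack([r * np.cos(phi), r * np.sin(phi)]) + np.asarray(center)
    return BlebOutline(verts)


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def ellipse_polygon():
    return make_ellipse_polygon


@pytest.fixture
def make_star_polygon():
    return star_polygon
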