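import numpy as np
import pytest
from shapely.geometry import Point, Polygon

from dcniche import SceneConfig, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_scene():
    """One deterministic synthetic scene shared across read-only tests."""
    return generate_scene(SceneConfig(n_dc=80, n_treg=40, n_other=60, seed=11))


def random_convex_polygon(rng, center, scale=10.0, n_vertices=8):
    """A random convex polygon: convex hull of points around a center."""
    pts = center + rng.normal(0, scale, size=(n_vertices, 2))
    return Polygon(pts).convex_hull


def disk(x, y, r=4.0):
    return Point(x, y).buffer(r, quad_segs=16)


def square(x0, y0, x1, y1):
    return Polygon([(x0, y0), (x1, y0), (x1, y1), (x0, y1)])
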