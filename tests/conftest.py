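import numpy as np
import pytest
from shapely.geometry import box

from aguadanet.landscape_io import StudyArea, Waterhole, WaterholeTable


def make_table(rows):
    """Build a WaterholeTable from (id, x, y, area) tuples."""
    return WaterholeTable(tuple(Waterhole(i, x, y, a) for i, x, y, a in rows))


def random_table(rng, n, extent=20_000.0, area_range=(800.0, 150_000.0)):
    xy = rng.random((n, 2)) * extent
    areas = rng.uniform(*area_range, size=n)
    return make_table(
        [(f"w{i}", xy[i, 0], xy[i, 1], areas[i]) for i in range(n)]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20140515)


@pytest.fixture
def tiny_table():
    """Three collinear waterholes at 0, 4 and 9 km."""
    return make_table(
        [("A", 0.0, 0.0, 1_000.0), ("B", 4_000.0, 0.0, 5_000.0),
         ("C", 9_000.0, 0.0, 80_000.0)]
    )


@pytest.fixture
def square_area():
    """30 x 25 km study area with a western reserve strip (35% of width)."""
    return StudyArea(
        boundary=box(0, 0, 30_000, 25_000),
        reserve=box(0, 0, 10_500, 25_000),
    )
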