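import numpy as np
import pytest
from shapely.geometry import LineString

from emaccess.facilities import FacilityRecord
from emaccess.roadnet import build_network


def record_from_attrs(attrs: dict, facility_id: str = "f") -> FacilityRecord:
    return FacilityRecord(facility_id=facility_id, x=0.0, y=0.0, **attrs)


def random_segments(rng: np.random.Generator, n: int, box_m: float,
                    seg_len: tuple[float, float] = (200.0, 800.0)):
    """Random straight 2-point segments in general position."""
    segs = []
    for _ in range(n):
        a = rng.uniform(0, box_m, size=2)
        ang = rng.uniform(0, 2 * np.pi)
        length = rng.uniform(*seg_len)
        b = a + length * np.array([np.cos(ang), np.sin(ang)])
        segs.append((tuple(a), tuple(b)))
    return segs


def random_network(rng: np.random.Generator, n_segments: int = 30,
                   box_m: float = 2000.0):
    segs = random_segments(rng, n_segments, box_m)
    return build_network([LineString([a, b]) for a, b in segs],
                         snap_tol_m=1e-6)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
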