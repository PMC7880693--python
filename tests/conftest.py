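import numpy as np
import pytest

from glandscan.io import PolygonROI
from glandscan.synthetic import (
    ChannelProfile,
    GlandSpec,
    ProfileSpec,
    make_gland_roi,
)


def random_simple_polygon(rng: np.random.Generator, n_max: int = 12) -> PolygonROI:
    """A random star-shaped (hence simple) polygon around a random center."""
    n = int(rng.integers(3, n_max + 1))
    # jittered evenly spaced angles: consecutive gaps stay < 180°, which
    # keeps the star-shaped construction simple for any radii
    angles = 2 * np.pi * (np.arange(n) + rng.uniform(0.05, 0.95, n)) / n
    angles += rng.uniform(0, 2 * np.pi)
    radii = rng.uniform(2.0, 30.0, n)
    cx, cy = rng.uniform(35, 65, 2)
    verts = np.column_stack(
        [cx + radii * np.cos(angles), cy + radii * np.sin(angles)]
    )
    return PolygonROI(verts)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def straight_gland():
    """Axis-aligned capsule, length 100, width 20, in a 120×160 frame."""
    return make_gland_roi(
        GlandSpec(length_px=100, width_px=20, image_shape=(120, 160))
    )


@pytest.fixture
def linear_profile_spec():
    return ProfileSpec(channels={"sig": ChannelProfile("linear", (0.0, 200.0))})
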