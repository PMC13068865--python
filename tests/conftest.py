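"""Shared fixtures: canonical synthetic shapes used across the suite."""

import numpy as np
import pytest

from msiseg import Mask2D, mask_to_contour
from msiseg.synthetic import ShapeSpec, render


@pytest.fixture
def disk_mask():
    """Radius-20 disk centered on a 64x64 grid."""
    return render(ShapeSpec("disk", {"center": (32, 32), "radius": 20}))


@pytest.fixture
def small_disk_mask():
    """Radius-10 disk concentric with ``disk_mask``."""
    return render(ShapeSpec("disk", {"center": (32, 32), "radius": 10}))


@pytest.fixture
def dumbbell_mask():
    """Two radius-10 disks, centers 30 px apart, joined by a 3-px bar."""
    return render(ShapeSpec(
        "dumbbell",
        {"centers": [(40, 25), (40, 55)], "radius": 10, "bar_width": 3},
        grid=(80, 80),
    ))


@pytest.fixture
def disk_contour(disk_mask):
    return mask_to_contour(disk_mask)


def random_contour_points(rng, n_max=200):
    """Random point cloud standing in for a contour (for oracle equivalence)."""
    n = int(rng.integers(3, n_max + 1))
    return rng.uniform(0, 100, size=(n, 2))


@pytest.fixture
def square_mask():
    pix = np.zeros((20, 20), dtype=bool)
    pix[5:15, 5:15] = True
    return Mask2D(pixels=pix)
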