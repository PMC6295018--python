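import numpy as np
import pytest

from shapescreen import synthetic_data as sd
from shapescreen.morphometry import MorphometryConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_config():
    return MorphometryConfig()


@pytest.fixture
def disk_field():
    """Single noiseless rasterised disk of radius 50 px."""
    return sd.generate_field([sd.shape_spec("disk", 50.0)], 160, seed=1)


def rasterized_square(side=60, canvas=120):
    mask = np.zeros((canvas, canvas), dtype=bool)
    lo = (canvas - side) // 2
    mask[lo:lo + side, lo:lo + side] = True
    return mask


def ramanujan_perimeter(a, b):
    """Ramanujan's ellipse-perimeter approximation (independent oracle)."""
    return np.pi * (3.0 * (a + b) - np.sqrt((3.0 * a + b) * (a + 3.0 * b)))


def ramanujan_circularity(aspect_ratio):
    """Analytic ellipse circularity using the Ramanujan perimeter."""
    a = np.sqrt(aspect_ratio)
    b = 1.0 / np.sqrt(aspect_ratio)
    area = np.pi * a * b
    return 4.0 * np.pi * area / ramanujan_perimeter(a, b) ** 2
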