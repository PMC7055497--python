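import numpy as np
import pytest

from cardiofiber import phantoms
from cardiofiber.volume_io import AnalysisConfig, Volume3D


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_config():
    """Analysis config scaled to small test volumes (window 32, stride 16)."""
    return AnalysisConfig(window_edge=32, stride=16, tissue_threshold=0.3,
                          min_tissue_fraction=0.05)


@pytest.fixture
def fiber_vol_z():
    """64^3 fiber phantom along z with mild noise, plus its ground truth."""
    vol, gt = phantoms.fiber_phantom(
        (64, 64, 64), "z", spacing=14, fiber_radius=3,
        noise_sigma=0.05, rng_seed=7)
    return vol, gt


@pytest.fixture
def noise_vol(rng):
    return Volume3D(rng.normal(size=(48, 48, 48)), 1.0)


def axial_angle_deg(a, b):
    """Axial (orientation, not direction) angle between unit vectors."""
    dot = abs(float(np.dot(a, b)))
    return float(np.degrees(np.arccos(min(1.0, dot))))
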