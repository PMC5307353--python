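import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from octmorph.geometry import ScalingParams
from octmorph.phantom import default_meta

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def meta():
    return default_meta()


@pytest.fixture
def unit_scales():
    return ScalingParams(axial_scale=1.0, lateral_scale=1.0)


@pytest.fixture
def aniso_scales():
    """In-water axial pitch vs wider lateral scan step."""
    return ScalingParams(axial_scale=9.0, lateral_scale=15.0)


def dft_direct(x: np.ndarray) -> np.ndarray:
    """Brute-force direct-sum DFT; the independent reconstruction oracle."""
    x = np.asarray(x, dtype=complex)
    n = len(x)
    j = np.arange(n)
    return np.array([np.sum(x * np.exp(-2j * np.pi * j * k / n)) for k in range(n)])
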