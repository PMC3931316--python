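import numpy as np
import pytest

from nmfpeaks import AxisCalibration, Spectrum


def gauss(n: int, center: float, width: float) -> np.ndarray:
    """Unit-apex 1D Gaussian on an n-point grid."""
    return np.exp(-((np.arange(n) - center) ** 2) / (2.0 * width * width))


@pytest.fixture
def rng():
    return np.random.default_rng(20240211)


@pytest.fixture
def hsqc_axes():
    return [
        AxisCalibration(64, 2430.0, 60.81, 118.0, "15N"),
        AxisCalibration(64, 2400.0, 600.13, 8.3, "1H"),
    ]


@pytest.fixture
def two_peak_spectrum(hsqc_axes):
    """Two well-separated Gaussian peaks on a 64x64 grid."""
    y = (1.0 * np.outer(gauss(64, 20, 2), gauss(64, 18, 2))
         + 0.5 * np.outer(gauss(64, 42, 2), gauss(64, 45, 2)))
    return Spectrum(y, hsqc_axes)
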