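import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import deepfascia as df

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def noiseless_phantom() -> df.PhantomOutput:
    """Default geometry with every corruption disabled."""
    return df.make_phantom(df.PhantomSpec(noise_sigma=0.0))


@pytest.fixture(scope="session")
def default_phantom() -> df.PhantomOutput:
    """Default geometry at the default Rician noise level."""
    return df.make_phantom(df.PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def striped_phantom() -> df.PhantomOutput:
    """Default noise plus sinusoidal interference at 32 cycles / 30 deg.

    Amplitude 0.2 (20% of muscle S0) makes the stripes strong enough to
    defeat intensity clustering when left uncorrected, which is the regime
    the FFT suppression stage exists for.
    """
    return df.make_phantom(
        df.PhantomSpec(seed=7, periodic_noise=(0.2, 32.0, 30.0))
    )


@pytest.fixture
def bar_mask():
    """Factory for an exact-width bar mask at a given orientation.

    Width is realized by the half-open band ``-w/2 <= d < w/2`` around the
    grid centre so an integer-width bar occupies exactly ``w`` pixels.
    """

    def make(width_px: float, angle_deg: float, size: int = 101, half_len: float = 35.0):
        c = (size - 1) / 2
        yy, xx = np.mgrid[0:size, 0:size].astype(float)
        t = np.radians(angle_deg)
        d = (yy - c) * np.cos(t) - (xx - c) * np.sin(t)
        along = (yy - c) * np.sin(t) + (xx - c) * np.cos(t)
        return (d >= -width_px / 2) & (d < width_px / 2) & (np.abs(along) <= half_len)

    return make
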