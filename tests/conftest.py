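import numpy as np
import pytest

from hemospec import (
    HRFKernel,
    HRFParams,
    SyntheticConfig,
    generate_subject,
    make_double_gamma_hrf,
)


@pytest.fixture(scope="session")
def std_kernel():
    """A mid-range double-gamma kernel (ttp 5 s, fwhm 4 s, unit peak)."""
    return make_double_gamma_hrf(HRFParams(ttp=5.0, fwhm=4.0, peak_psc=1.0), dt=0.1)


@pytest.fixture(scope="session")
def fast_slow_kernels():
    fast = make_double_gamma_hrf(HRFParams(ttp=4.0, fwhm=3.0, peak_psc=1.0), dt=0.1)
    slow = make_double_gamma_hrf(HRFParams(ttp=5.5, fwhm=4.5, peak_psc=1.0), dt=0.1)
    return fast, slow


def impulse_kernel(dt: float, duration: float = 32.0) -> HRFKernel:
    """Unit impulse at t=0 (single nonzero sample 1/dt): identity of convolution."""
    n = int(round(duration / dt)) + 1
    samples = np.zeros(n)
    samples[0] = 1.0 / dt
    return HRFKernel.from_samples(samples, dt)


@pytest.fixture(scope="session")
def small_subject():
    """A small synthetic subject shared by the slower integration tests."""
    return generate_subject(SyntheticConfig(n_per_class=20, seed=11))


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(n_per_class=20, seed=11)
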