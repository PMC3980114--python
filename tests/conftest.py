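import numpy as np
import pytest

from flimfret.model import DecayParams, IRFCurve


@pytest.fixture
def irf_delta():
    """Unit-impulse IRF on the 64-channel / 12.5 ns grid."""
    return IRFCurve.delta(64)


@pytest.fixture
def irf_gauss():
    """Narrow Gaussian IRF (sigma 0.1 ns) like a measured SHG response."""
    return IRFCurve.gaussian(64, sigma=0.1, center=0.25)


@pytest.fixture
def params_mixed():
    """Representative two-state mixture (30% FRET amplitude fraction)."""
    return DecayParams(f0=1000.0, p_free=0.7, tau_free=2.6, tau_fret=1.1)


def brute_force_circular_conv(a, b):
    """O(N^2) direct-sum periodic convolution (independent oracle)."""
    n = len(a)
    out = np.zeros(n)
    for k in range(n):
        for j in range(n):
            out[k] += a[j] * b[(k - j) % n]
    return out
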