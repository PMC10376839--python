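"""Shared fixtures and independent numerical oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest

from crnn_dwi import default_scheme


# -- high-precision Mittag-Leffler oracle -----------------------------------


def ml_oracle_value(alpha: float, z: float, digits: int = 50) -> float:
    """Arbitrary-precision reference for E_alpha(z), z <= 0.

    Truncated series summation carried out in mpmath with the working
    precision raised far enough above the largest (alternating) term that
    the final sum keeps ``digits`` significant digits.  For alpha = 1 and
    alpha = 1/2 exact closed forms are used instead (exp, and the
    scaled-complementary-error-function identity E_1/2(z) = e^{z^2} erfc(-z)),
    which keeps the oracle fast at large |z|.
    """
    import mpmath as mp
    from scipy.special import gammaln

    if z == 0:
        return 1.0
    if alpha == 1.0:
        mp.mp.dps = digits
        return float(mp.e ** mp.mpf(z))
    if alpha == 0.5:
        x = -mp.mpf(z)
        mp.mp.dps = max(digits, int(float(x) * float(x) / 2.3) + digits)
        return float(mp.e ** (x * x) * mp.erfc(x))
    az = abs(z)
    ks = np.arange(0, 50000)
    logt = ks * math.log(az) - gammaln(alpha * ks + 1)
    k_peak = int(ks[np.argmax(logt)])
    mp.mp.dps = int(max(logt.max() / math.log(10), 0)) + digits
    s = mp.mpf(0)
    t = mp.mpf(1)
    zz = mp.mpf(z)
    ga = mp.mpf(alpha)
    k = 0
    while True:
        s += t
        k += 1
        t = zz**k / mp.gamma(ga * k + 1)
        if k > k_peak and abs(t) < mp.mpf(10) ** (-digits):
            break
    return float(s)


@pytest.fixture(scope="session")
def ml_oracle():
    return ml_oracle_value


@pytest.fixture(scope="session")
def scheme14():
    """The default 14-b-value, 3-direction acquisition scheme."""
    return default_scheme()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
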