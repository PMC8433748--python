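"""Independent numerical oracles for the concentration model.

The monomer concentration is reconstructed by numerically double-integrating
the Gaussian curvature (the model's defining object) with the boundary
conditions d[S1]/d[S]0 -> 0 far above the cmc and [S1] -> cmc at the
plateau; the normalization amplitude is found by root bracketing on the
condition [S1](0) = 0.  No error-function closed form is used anywhere, so
these routines are an independent check of the analytic model.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

# integrate to cmc + _TAIL*sigma: the Gaussian tail beyond is < 1e-31
_TAIL = 12.0


def _gauss(t: float, cmc: float, sigma: float) -> float:
    return np.exp(-((t - cmc) ** 2) / (2.0 * sigma**2)) / (np.sqrt(2.0 * np.pi) * sigma)


def s1_double_integral(s0: float, cmc: float, r: float, amp: float) -> float:
    """[S1](s0) from the double integral of the Gaussian curvature.

    Uses Fubini to collapse the iterated integral
    int_s0^inf int_t^inf g(u) du dt  =  int_s0^inf (u - s0) g(u) du,
    then [S1](s0) = cmc - amp * (that integral).
    """
    sigma = r * cmc
    hi = cmc + _TAIL * sigma
    if s0 >= hi:
        return cmc
    val, _ = quad(
        lambda u: (u - s0) * _gauss(u, cmc, sigma), s0, hi, epsabs=1e-13, epsrel=1e-13, limit=200
    )
    return cmc - amp * val


def amplitude_bisection(r: float) -> float:
    """Normalization amplitude: the value that makes [S1](0) = 0."""
    f = lambda a: s1_double_integral(0.0, 1.0, r, a)
    return brentq(f, 0.1, 4.0, xtol=1e-14, rtol=1e-15)
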