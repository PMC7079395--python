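"""Regularized lower incomplete gamma function and its inverse, numba-jitted.

The MCMC sweep loop is compiled with numba, and updating the gamma shape
parameter inside a sweep requires re-discretizing the mean-1 gamma rate
distribution, which needs ``P(a, x)`` and its inverse in nopython code.
These are classic series / continued-fraction evaluations with a
Halley-refined inverse; they are checked against ``scipy.special`` in the
test suite to 1e-10.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_EPS = 2.22e-16
_FPMIN = 1e-300


@njit(cache=True)
def gammainc_lower(a: float, x: float) -> float:
    """Regularized lower incomplete gamma function P(a, x)."""
    if x < 0.0 or a <= 0.0:
        return np.nan
    if x == 0.0:
        return 0.0
    if x < a + 1.0:
        # Series representation.
        ap = a
        summ = 1.0 / a
        term = summ
        for _ in range(10000):
            ap += 1.0
            term *= x / ap
            summ += term
            if abs(term) < abs(summ) * _EPS:
                break
        return summ * math.exp(-x + a * math.log(x) - math.lgamma(a))
    # Continued fraction for Q(a, x), modified Lentz.
    b = x + 1.0 - a
    c = 1.0 / _FPMIN
    d = 1.0 / b
    h = d
    for i in range(1, 10000):
        an = -i * (i - a)
        b += 2.0
        d = an * d + b
        if abs(d) < _FPMIN:
            d = _FPMIN
        c = b + an / c
        if abs(c) < _FPMIN:
            c = _FPMIN
        d = 1.0 / d
        delta = d * c
        h *= delta
        if abs(delta - 1.0) < _EPS:
            break
    q = math.exp(-x + a * math.log(x) - math.lgamma(a)) * h
    return 1.0 - q


@njit(cache=True)
def gammainc_inv(a: float, p: float) -> float:
    """Inverse of P(a, .): x such that gammainc_lower(a, x) == p."""
    if a <= 0.0:
        return np.nan
    if p >= 1.0:
        return max(100.0, a + 100.0 * math.sqrt(a))
    if p <= 0.0:
        return 0.0
    gln = math.lgamma(a)
    a1 = a - 1.0
    lna1 = 0.0
    afac = 0.0
    if a > 1.0:
        lna1 = math.log(a1)
        afac = math.exp(a1 * (lna1 - 1.0) - gln)
        pp = p if p < 0.5 else 1.0 - p
        t = math.sqrt(-2.0 * math.log(pp))
        x = (2.30753 + t * 0.27061) / (1.0 + t * (0.99229 + t * 0.04481)) - t
        if p < 0.5:
            x = -x
        x = max(1e-3, a * (1.0 - 1.0 / (9.0 * a) - x / (3.0 * math.sqrt(a))) ** 3)
    else:
        t = 1.0 - a * (0.253 + a * 0.12)
        if p < t:
            x = (p / t) ** (1.0 / a)
        else:
            x = 1.0 - math.log(1.0 - (p - t) / (1.0 - t))
    for _ in range(20):
        if x <= 0.0:
            return 0.0
        err = gammainc_lower(a, x) - p
        if a > 1.0:
            t = afac * math.exp(-(x - a1) + a1 * (math.log(x) - lna1))
        else:
            t = math.exp(-x + a1 * math.log(x) - gln)
        if t == 0.0:
            break
        u = err / t
        # Halley step.
        t = u / (1.0 - 0.5 * min(1.0, u * (a1 / x - 1.0)))
        x -= t
        if x <= 0.0:
            x = 0.5 * (x + t)
        if abs(t) < _EPS * x:
            break
    return x


@njit(cache=True)
def discretize_gamma_rates(alpha: float, out: np.ndarray) -> None:
    """Mean-of-slice discretization of Gamma(alpha, mean 1) into K categories.

    Writes the K ascending rates into ``out`` (length K), renormalized so
    their mean is exactly 1.  Mirrors :func:`iwesse.model_core.discretize_gamma`.
    """
    K = out.shape[0]
    prev_cdf = 0.0
    total = 0.0
    for k in range(K):
        if k == K - 1:
            upper_cdf = 1.0
        else:
            bound = gammainc_inv(alpha, (k + 1.0) / K) / alpha
            upper_cdf = gammainc_lower(alpha + 1.0, alpha * bound)
        out[k] = K * (upper_cdf - prev_cdf)
        prev_cdf = upper_cdf
        total += out[k]
    mean = total / K
    for k in range(K):
        out[k] /= mean
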