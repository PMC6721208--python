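"""Exact Polya-Gamma sampling.

The logistic likelihood becomes conditionally Gaussian after augmenting each
observation with an auxiliary variable ``omega_i ~ PG(1, psi_i)``; this module
provides exact draws from the Polya-Gamma distribution PG(b, c) using the
alternating-series rejection sampler of Devroye (the same construction used by
standard PG libraries), compiled with numba for speed.

Useful identities used by the test-suite:
``E[PG(b, c)] = b / (2 c) * tanh(c / 2)`` with the limit ``b / 4`` at c = 0.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["draw_polya_gamma", "pg_vector"]

_TRUNC = 0.64  # crossover point of the two J*(1, z) density bounds


@njit(cache=True)
def _norm_cdf(x):
    return 0.5 * math.erfc(-x / math.sqrt(2.0))


@njit(cache=True)
def _pigauss(t, z):
    # CDF at t of an inverse-Gaussian(mu=1/z, lambda=1); z = 0 means mu = inf.
    if t <= 0.0:
        return 0.0
    rt = math.sqrt(t)
    if z == 0.0:
        return 2.0 * _norm_cdf(-1.0 / rt)
    return _norm_cdf((t * z - 1.0) / rt) + math.exp(2.0 * z) * _norm_cdf(
        -(t * z + 1.0) / rt
    )


@njit(cache=True)
def _acoef(n, x, t):
    # Piecewise coefficients of the alternating series bounding the J* density.
    h = n + 0.5
    if x > t:
        return math.pi * h * math.exp(-h * h * math.pi * math.pi * x / 2.0)
    return math.pi * h * (2.0 / (math.pi * x)) ** 1.5 * math.exp(-2.0 * h * h / x)


@njit(cache=True)
def _draw_jstar(z):
    # One exact draw of J*(1, z) for z >= 0; PG(1, c) = J*(1, |c|/2) / 4.
    t = _TRUNC
    K = math.pi * math.pi / 8.0 + z * z / 2.0
    p = math.pi / (2.0 * K) * math.exp(-K * t)
    q = 2.0 * math.exp(-z) * _pigauss(t, z)
    mu = 1.0e308 if z == 0.0 else 1.0 / z
    while True:
        if np.random.random() < p / (p + q):
            # proposal from the truncated exponential tail on (t, inf)
            x = t + np.random.exponential() / K
        else:
            # proposal from the inverse-Gaussian body truncated to (0, t)
            if mu > t:
                while True:
                    while True:
                        e1 = np.random.exponential()
                        e2 = np.random.exponential()
                        if e1 * e1 <= 2.0 * e2 / t:
                            break
                    x = t / ((1.0 + t * e1) * (1.0 + t * e1))
                    if np.random.random() <= math.exp(-z * z * x / 2.0):
                        break
            else:
                while True:
                    y = np.random.standard_normal()
                    y = y * y
                    x = (
                        mu
                        + 0.5 * mu * mu * y
                        - 0.5 * mu * math.sqrt(4.0 * mu * y + (mu * y) * (mu * y))
                    )
                    if np.random.random() > mu / (mu + x):
                        x = mu * mu / x
                    if x <= t:
                        break
        # accept/reject by partial sums of the alternating series
        s = _acoef(0, x, t)
        yv = np.random.random() * s
        n = 0
        while True:
            n += 1
            if n % 2 == 1:
                s -= _acoef(n, x, t)
                if yv <= s:
                    return x
            else:
                s += _acoef(n, x, t)
                if yv > s:
                    break


@njit(cache=True)
def _pg_array(b, c, n, seed):
    np.random.seed(seed)
    out = np.empty(n)
    z = abs(c) / 2.0
    for i in range(n):
        acc = 0.0
        for _ in range(b):
            acc += _draw_jstar(z)
        out[i] = acc / 4.0
    return out


@njit(cache=True)
def _pg_vector(c, seed):
    np.random.seed(seed)
    out = np.empty(c.shape[0])
    for i in range(c.shape[0]):
        out[i] = _draw_jstar(abs(c[i]) / 2.0) / 4.0
    return out


def draw_polya_gamma(b, c, rng, size=None):
    """Draw from PG(b, c) for positive integer shape ``b``.

    Parameters
    ----------
    b : int
        Shape parameter (must be a positive integer; PG(b, c) is sampled as a
        b-fold convolution of PG(1, c)).
    c : float
        Tilting parameter.
    rng : numpy.random.Generator
        Source of randomness (a derived seed drives the compiled sampler).
    size : int, optional
        Number of draws; a scalar is returned when omitted.
    """
    if b <= 0:
        raise ValueError(f"PG shape parameter b must be positive, got {b}")
    if int(b) != b:
        raise NotImplementedError("only integer b is supported")
    seed = int(rng.integers(0, 2**31 - 1))
    n = 1 if size is None else int(size)
    out = _pg_array(int(b), float(c), n, seed)
    return float(out[0]) if size is None else out


def pg_vector(c, rng):
    """One PG(1, c_i) draw per element of ``c`` (used by the Gibbs sweep)."""
    c = np.ascontiguousarray(c, dtype=np.float64)
    if c.size == 0:
        return np.empty(0)
    seed = int(rng.integers(0, 2**31 - 1))
    return _pg_vector(c, seed)
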