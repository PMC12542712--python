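"""Exact Pólya-Gamma PG(1, z) sampling.

The augmentation variable behind the logistic Gibbs sampler: if
omega ~ PG(1, eta) then the Bernoulli-logit likelihood becomes Gaussian in
the linear predictor, giving closed-form full conditionals for every
intercept block. Sampling uses the alternating-series rejection sampler for
the Jacobi J*(1, z) density (proposal: truncated inverse-Gaussian below the
crossover point t = 0.64, truncated exponential above), which is exact —
no truncation of the infinite sum is ever accepted on faith.

Scalar kernels are numba-jitted; the public entry point is vectorised over
the linear predictor.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_TRUNC = 0.64  # proposal crossover point, 2/pi


@njit(cache=True)
def _norm_cdf(x):
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


@njit(cache=True)
def _a_coef(n, x):
    # n-th alternating-series coefficient of the J*(1,.) density at x
    if x > _TRUNC:
        return math.pi * (n + 0.5) * math.exp(-((n + 0.5) ** 2) * math.pi ** 2 * x / 2.0)
    return (
        math.pi
        * (n + 0.5)
        * (2.0 / (math.pi * x)) ** 1.5
        * math.exp(-2.0 * (n + 0.5) ** 2 / x)
    )


@njit(cache=True)
def _mass_texpon(z):
    # P(proposal comes from the exponential right tail)
    fz = math.pi ** 2 / 8.0 + z * z / 2.0
    b = math.sqrt(1.0 / _TRUNC) * (_TRUNC * z - 1.0)
    a = -math.sqrt(1.0 / _TRUNC) * (_TRUNC * z + 1.0)
    x0 = math.log(fz) + fz * _TRUNC
    xb = x0 - z + math.log(_norm_cdf(b))
    xa = x0 + z + math.log(_norm_cdf(a))
    qdivp = 4.0 / math.pi * (math.exp(xb) + math.exp(xa))
    return 1.0 / (1.0 + qdivp)


@njit(cache=True)
def _rtigauss(z):
    # inverse-Gaussian(mu=1/z, lambda=1) truncated to (0, TRUNC]
    z = abs(z)
    x = _TRUNC + 1.0
    if _TRUNC * z < 1.0:  # mu > TRUNC: rejection from scaled chi^-2
        alpha = 0.0
        while np.random.rand() > alpha:
            e1 = np.random.exponential(1.0)
            e2 = np.random.exponential(1.0)
            while e1 * e1 > 2.0 * e2 / _TRUNC:
                e1 = np.random.exponential(1.0)
                e2 = np.random.exponential(1.0)
            x = _TRUNC / (1.0 + _TRUNC * e1) ** 2
            alpha = math.exp(-0.5 * z * z * x)
    else:
        mu = 1.0 / z
        while x > _TRUNC:
            y = np.random.standard_normal() ** 2
            half = mu + 0.5 * mu * mu * y - 0.5 * mu * math.sqrt(4.0 * mu * y + (mu * y) ** 2)
            x = half
            if np.random.rand() > mu / (mu + x):
                x = mu * mu / x
    return x


@njit(cache=True)
def _sample_pg1(c):
    """One draw from PG(1, c)."""
    z = abs(c) / 2.0
    fz = math.pi ** 2 / 8.0 + z * z / 2.0
    while True:
        if np.random.rand() < _mass_texpon(z):
            x = _TRUNC + np.random.exponential(1.0) / fz
        else:
            x = _rtigauss(z)
        s = _a_coef(0, x)
        y = np.random.rand() * s
        n = 0
        accepted = False
        rejected = False
        while not (accepted or rejected):
            n += 1
            if n % 2 == 1:
                s -= _a_coef(n, x)
                if y <= s:
                    accepted = True
            else:
                s += _a_coef(n, x)
                if y > s:
                    rejected = True
        if accepted:
            return x / 4.0


@njit(cache=True)
def _draw_pg_seeded(c, seed):
    np.random.seed(seed)
    out = np.empty(c.shape[0])
    for i in range(c.shape[0]):
        out[i] = _sample_pg1(c[i])
    return out


def draw_pg(c: np.ndarray, seed: int) -> np.ndarray:
    """Draw omega_i ~ PG(1, c_i) elementwise, deterministically for a seed.

    Parameters
    ----------
    c
        Linear predictors (any sign; PG tilting depends on ``|c|``).
    seed
        Seed for the internal generator; identical (c, seed) pairs give
        bit-identical output.
    """
    c = np.ascontiguousarray(np.asarray(c, dtype=np.float64))
    return _draw_pg_seeded(c, np.uint32(seed % (2 ** 32)))
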