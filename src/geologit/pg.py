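"""Exact Pólya-Gamma PG(1, z) sampling.

PG augmentation turns the Bernoulli-logit likelihood into a
conditionally Gaussian one: with ``omega_i ~ PG(1, eta_i)`` the
augmented likelihood is Gaussian in the linear predictor with precision
``omega_i`` and working response ``(y_i - 1/2)/omega_i``.  A PG(1, z)
variable is ``J*(1, z/2)/4`` where ``J*`` is a Jacobi random variable;
it is sampled here with the exact alternating-series rejection sampler
of the Devroye type, mixing a truncated inverse-Gaussian with an
exponential tail at the crossover point 0.64.  The mean identity

    E[PG(1, z)] = tanh(z/2) / (2 z)   (limit 1/4 at z = 0)

is the closed-form oracle used by the tests.

The inner sampler is a scalar loop JIT-compiled with numba; a draw of
the whole latent vector is seeded explicitly so Gibbs runs are
reproducible.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["sample_polya_gamma", "draw_pg_vector", "pg_mean"]

_TRUNC = 0.64
_PI = math.pi


def pg_mean(z: float | np.ndarray) -> float | np.ndarray:
    """Closed-form mean of PG(1, z)."""
    z = np.asarray(z, dtype=float)
    out = np.where(z == 0.0, 0.25, np.tanh(z / 2.0) / np.where(z == 0.0, 1.0, 2.0 * z))
    return out.item() if out.ndim == 0 else out


@njit(cache=True)
def _norm_cdf(x):
    return 0.5 * math.erfc(-x / math.sqrt(2.0))


@njit(cache=True)
def _mass_texpon(z):
    # probability that the proposal comes from the exponential tail
    t = _TRUNC
    fz = 0.125 * _PI * _PI + 0.5 * z * z
    b = math.sqrt(1.0 / t) * (t * z - 1.0)
    a = -math.sqrt(1.0 / t) * (t * z + 1.0)
    x0 = math.log(fz) + fz * t
    cb = _norm_cdf(b)
    ca = _norm_cdf(a)
    xb = x0 - z + (math.log(cb) if cb > 0.0 else -np.inf)
    xa = x0 + z + (math.log(ca) if ca > 0.0 else -np.inf)
    qdivp = 4.0 / _PI * (math.exp(xb) + math.exp(xa))
    return 1.0 / (1.0 + qdivp)


@njit(cache=True)
def _rtigauss(z):
    # inverse-Gaussian(mu=1/z, lambda=1) truncated to (0, _TRUNC]
    t = _TRUNC
    x = t + 1.0
    if z < 1.0 / t:  # mu > t: rejection from the chi-like proposal
        alpha = 0.0
        while np.random.random() > alpha:
            e1 = np.random.exponential()
            e2 = np.random.exponential()
            while e1 * e1 > 2.0 * e2 / t:
                e1 = np.random.exponential()
                e2 = np.random.exponential()
            x = t / ((1.0 + t * e1) * (1.0 + t * e1))
            alpha = math.exp(-0.5 * z * z * x)
    else:
        mu = 1.0 / z
        while x > t:
            y = np.random.normal()
            y = y * y
            half = 0.5 * mu
            muy = mu * y
            x = mu + half * mu * y - half * math.sqrt(4.0 * muy + muy * muy)
            if np.random.random() > mu / (mu + x):
                x = mu * mu / x
    return x


@njit(cache=True)
def _a_coef(n, x):
    # n-th term of the alternating series for the J*(1, .) density
    nph = n + 0.5
    if x > _TRUNC:
        return _PI * nph * math.exp(-0.5 * nph * nph * _PI * _PI * x)
    return (
        _PI * nph * math.pow(2.0 / (_PI * x), 1.5) * math.exp(-2.0 * nph * nph / x)
    )


@njit(cache=True)
def _sample_pg1(z):
    z = 0.5 * abs(z)
    fz = 0.125 * _PI * _PI + 0.5 * z * z
    while True:
        if np.random.random() < _mass_texpon(z):
            x = _TRUNC + np.random.exponential() / fz
        else:
            x = _rtigauss(z)
        s = _a_coef(0, x)
        y = np.random.random() * s
        n = 0
        while True:
            n += 1
            if n % 2 == 1:
                s -= _a_coef(n, x)
                if y <= s:
                    return 0.25 * x
            else:
                s += _a_coef(n, x)
                if y > s:
                    break


@njit(cache=True)
def _draw_vector(zs, seed):
    np.random.seed(seed)
    out = np.empty(zs.shape[0])
    for i in range(zs.shape[0]):
        out[i] = _sample_pg1(zs[i])
    return out


def draw_pg_vector(z: np.ndarray, seed: int) -> np.ndarray:
    """Draw one PG(1, z_i) per element of ``z``; deterministic given seed."""
    z = np.ascontiguousarray(z, dtype=np.float64)
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite value in PG argument vector")
    return _draw_vector(z, int(seed) % (2**32 - 1))


def sample_polya_gamma(z: float, rng: np.random.Generator) -> float:
    """One exact draw from PG(1, z)."""
    if not math.isfinite(z):
        raise ValueError("z must be finite")
    seed = int(rng.integers(0, 2**31 - 1))
    return float(_draw_vector(np.array([float(z)]), seed)[0])
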