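"""Exact Pólya–Gamma PG(1, z) sampling for logistic data augmentation.

A Bernoulli-logit likelihood becomes conditionally Gaussian once each
observation is augmented with ω ~ PG(1, η): the exact alternating-series
rejection sampler of Devroye draws from the tilted Jacobi distribution
J*(1, z/2), and PG(1, z) = J*(1, z/2) / 4.  The inner loops are compiled
with numba so a full sweep over tens of thousands of cells costs
milliseconds.

Closed forms used by the tests:
    E[PG(1, z)]  = tanh(z/2) / (2 z)
    Var[PG(1,z)] = (sinh(z) - z) / (4 z^3 cosh^2(z/2))
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_TRUNC = 0.64  # crossover point between the two series representations


@njit(cache=True)
def _log_phi(x: float) -> float:
    """log of the standard normal CDF, stable in the far left tail."""
    if x > -8.0:
        return math.log(0.5 * math.erfc(-x / math.sqrt(2.0)))
    x2 = x * x
    return -0.5 * x2 - math.log(-x) - 0.5 * math.log(2.0 * math.pi) + math.log1p(
        -1.0 / x2 + 3.0 / (x2 * x2)
    )


@njit(cache=True)
def _mass_texpon(z: float) -> float:
    """P(proposal comes from the truncated-exponential right piece)."""
    t = _TRUNC
    fz = 0.125 * math.pi * math.pi + 0.5 * z * z
    b = math.sqrt(1.0 / t) * (t * z - 1.0)
    a = -math.sqrt(1.0 / t) * (t * z + 1.0)
    x0 = math.log(fz) + fz * t
    xb = x0 - z + _log_phi(b)
    xa = x0 + z + _log_phi(a)
    qdivp = 4.0 / math.pi * (math.exp(xb) + math.exp(xa))
    return 1.0 / (1.0 + qdivp)


@njit(cache=True)
def _rtigauss(z: float, gen) -> float:
    """Inverse-Gaussian IG(1/z, 1) truncated to (0, _TRUNC]."""
    t = _TRUNC
    x = t + 1.0
    if 1.0 / t < z:  # mu < t: ordinary IG draw, rejection on the tail
        mu = 1.0 / z
        while x > t:
            y = gen.standard_normal()
            y = y * y
            half_mu = 0.5 * mu
            mu_y = mu * y
            x = mu + half_mu * mu_y - half_mu * math.sqrt(4.0 * mu_y + mu_y * mu_y)
            if gen.random() > mu / (mu + x):
                x = mu * mu / x
    else:  # heavy-tailed regime: chi-square style proposal on (0, t]
        while True:
            e1 = gen.standard_exponential()
            e2 = gen.standard_exponential()
            while e1 * e1 > 2.0 * e2 / t:
                e1 = gen.standard_exponential()
                e2 = gen.standard_exponential()
            x = t / ((1.0 + t * e1) * (1.0 + t * e1))
            if gen.random() <= math.exp(-0.5 * z * z * x):
                break
    return x


@njit(cache=True)
def _series_coef(n: int, x: float) -> float:
    """Alternating-series coefficient a_n(x) of the Jacobi density."""
    nph = n + 0.5
    if x <= _TRUNC:
        return (
            math.pi
            * nph
            * math.pow(2.0 / (math.pi * x), 1.5)
            * math.exp(-2.0 * nph * nph / x)
        )
    return math.pi * nph * math.exp(-0.5 * nph * nph * math.pi * math.pi * x)


@njit(cache=True)
def _draw_pg1(z: float, gen) -> float:
    """One exact PG(1, z) draw via Devroye's rejection sampler."""
    z = 0.5 * abs(z)
    fz = 0.125 * math.pi * math.pi + 0.5 * z * z
    p_right = _mass_texpon(z)
    while True:
        if gen.random() < p_right:
            x = _TRUNC + gen.standard_exponential() / fz
        else:
            x = _rtigauss(z, gen)
        s = _series_coef(0, x)
        y = gen.random() * s
        n = 0
        while True:
            n += 1
            if n % 2 == 1:
                s -= _series_coef(n, x)
                if y <= s:
                    return 0.25 * x
            else:
                s += _series_coef(n, x)
                if y > s:
                    break


@njit(cache=True)
def _draw_many(z: np.ndarray, out: np.ndarray, gen) -> None:
    for i in range(z.size):
        out[i] = _draw_pg1(z[i], gen)


def random_polya_gamma(z, rng: np.random.Generator) -> np.ndarray:
    """Vector of independent PG(1, z_i) draws (exact, no approximation)."""
    z = np.ascontiguousarray(np.asarray(z, dtype=np.float64).ravel())
    out = np.empty_like(z)
    _draw_many(z, out, rng)
    return out


def pg_mean(z) -> np.ndarray:
    """E[PG(1, z)] = tanh(z/2)/(2z), with the z->0 limit 1/4."""
    z = np.asarray(z, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.tanh(z / 2.0) / (2.0 * z)
    return np.where(np.abs(z) < 1e-8, 0.25, m)


def pg_var(z) -> np.ndarray:
    """Var[PG(1, z)]; the z->0 limit is 1/24."""
    z = np.asarray(z, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        v = (np.sinh(z) - z) / (4.0 * z**3 * np.cosh(z / 2.0) ** 2)
    return np.where(np.abs(z) < 1e-4, 1.0 / 24.0, v)


def random_polya_gamma_series(
    z, rng: np.random.Generator, n_terms: int = 2000
) -> np.ndarray:
    """Independent reference sampler from the infinite-sum representation.

    PG(1, z) = (1/(2π²)) Σ_k g_k / ((k-1/2)² + z²/(4π²)), g_k ~ Exp(1),
    truncated at *n_terms* with the truncated tail replaced by its exact
    expectation.  Slow and approximate: used only as an independent oracle
    in tests, never inside the sampler.
    """
    z = np.asarray(z, dtype=float).ravel()
    k = np.arange(1, n_terms + 1)
    denom = (k - 0.5) ** 2 + z[:, None] ** 2 / (4.0 * math.pi**2)
    g = rng.standard_exponential(size=(z.size, n_terms))
    draws = (g / denom).sum(axis=1) / (2.0 * math.pi**2)
    tail = pg_mean(z) - (1.0 / denom).sum(axis=1) / (2.0 * math.pi**2)
    return draws + tail
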