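"""Classical (no-sampling) linear birth--death transition probabilities.

For a linear birth--death process with per-capita birth rate lambda and
death rate mu, the single-lineage law at time t is geometric:

    p_{1,0}(t) = alpha,
    p_{1,m}(t) = (1 - alpha) (1 - beta) beta^(m-1),   m >= 1,

with, writing r = lambda - mu,

    alpha = mu (e^{rt} - 1) / (lambda e^{rt} - mu),
    beta  = lambda (e^{rt} - 1) / (lambda e^{rt} - mu),

and alpha = beta = lambda t / (1 + lambda t) in the critical case
lambda = mu.  Starting from n independent lineages the transition
probability p_{n,m}(t) is the n-fold convolution of this law, which has
the closed form implemented in :func:`transition_probability`.

The interchange-symmetric scaling

    ptilde_{n,m}(t | lambda, mu) = lambda^n mu^m p_{n,m}(t | lambda, mu)

is invariant under swapping lambda and mu; :func:`transition_oracle`
provides an independent generator-exponential cross-check.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import poisson

from .params import RatePair, TruncationError

__all__ = [
    "transition_probability",
    "log_transition_probability",
    "tilde_transition",
    "transition_oracle",
]

# Critical-case switch: treat lambda ~ mu as critical when |lambda-mu| t is
# below this factor times (1 + lambda t); alpha and beta are continuous in
# r = lambda - mu and their expm1 forms stay accurate down to machine
# precision, so the switch sits there (the critical approximation error it
# admits is O(1e-13)).
_CRITICAL_REL = 1e-13


def _validate(n: int, m: int, t: float) -> None:
    if int(n) != n or n < 1:
        raise ValueError(f"n must be an integer >= 1, got {n}")
    if int(m) != m or m < 0:
        raise ValueError(f"m must be an integer >= 0, got {m}")
    if not (math.isfinite(t) and t >= 0.0):
        raise ValueError(f"t must be finite and >= 0, got {t}")


def _alpha_beta(t: float, rates: RatePair) -> tuple[float, float, float, float]:
    """(alpha, beta, 1-alpha, 1-beta) of the single-lineage geometric law.

    The complements are computed in closed form (1-alpha = r/denom etc.),
    not as 1.0 - alpha: for rates ~100 the direct subtraction cancels
    catastrophically while the products r x / denom stay accurate.
    """
    lam, mu = rates.birth_rate, rates.death_rate
    if abs(lam - mu) * t < _CRITICAL_REL * (1.0 + lam * t):
        a = lam * t / (1.0 + lam * t)
        c = 1.0 / (1.0 + lam * t)
        return a, a, c, c
    r = lam - mu
    if r > 0.0:
        # multiply through by e^{-rt}: denominator lambda - mu e^{-rt}
        one_minus = -math.expm1(-r * t)          # 1 - e^{-rt}
        denom = r + mu * one_minus               # = lambda - mu e^{-rt} > 0
        one_m_alpha = r / denom
        one_m_beta = r * math.exp(-r * t) / denom
    else:
        one_minus = -math.expm1(r * t)           # 1 - e^{rt}
        denom = -r + lam * one_minus             # = mu - lambda e^{rt} > 0
        one_m_alpha = -r * math.exp(r * t) / denom
        one_m_beta = -r / denom
    return mu * one_minus / denom, lam * one_minus / denom, one_m_alpha, one_m_beta


def transition_probability(n: int, m: int, t: float, rates: RatePair) -> float:
    """Probability p_{n,m}(t | lambda, mu) of m individuals after time t, from n.

    Exact closed form: the n-fold composition of the single-lineage
    geometric law,

        p_{n,0} = alpha^n,
        p_{n,m} = sum_{j=1}^{min(n,m)} C(n,j) alpha^{n-j}
                  [(1-alpha)(1-beta)]^j C(m-1,j-1) beta^{m-j},  m >= 1,

    where j counts the initial lineages with surviving descent.
    """
    _validate(n, m, t)
    alpha, beta, one_m_alpha, one_m_beta = _alpha_beta(t, rates)
    if m == 0:
        return alpha ** n
    core = one_m_alpha * one_m_beta
    total = 0.0
    for j in range(1, min(n, m) + 1):
        total += (
            math.comb(n, j)
            * alpha ** (n - j)
            * core ** j
            * math.comb(m - 1, j - 1)
            * beta ** (m - j)
        )
    return total


def log_transition_probability(n: int, m: int, t: float, rates: RatePair) -> float:
    """log p_{n,m}(t); stable for the single-lineage geometric tail at large m."""
    _validate(n, m, t)
    alpha, beta, one_m_alpha, one_m_beta = _alpha_beta(t, rates)
    if n == 1 and m >= 1:
        if beta == 0.0:
            return -math.inf if m > 1 else math.log(one_m_alpha)
        return math.log(one_m_alpha) + math.log(one_m_beta) + (m - 1) * math.log(beta)
    p = transition_probability(n, m, t, rates)
    return math.log(p) if p > 0.0 else -math.inf


def tilde_transition(n: int, m: int, t: float, rates: RatePair) -> float:
    """The interchange-symmetric scaling lambda^n mu^m p_{n,m}(t | lambda, mu).

    Satisfies tilde(n, m, t, (lambda, mu)) == tilde(n, m, t, (mu, lambda)).
    """
    p = transition_probability(n, m, t, rates)
    return rates.birth_rate ** n * rates.death_rate ** m * p


def transition_oracle(n: int, t: float, rates: RatePair, truncation: int) -> np.ndarray:
    """Brute-force transition distribution via the generator exponential.

    Evaluates exp(t Q) e_n for the birth--death generator Q on states
    0..truncation (birth rate k*lambda and death rate k*mu from state k)
    by uniformization: the Poisson-weighted power series of the
    uniformized kernel P = I + Q/Lambda, applied in time chunks so the
    Poisson weights stay representable.  Births out of the top state are
    routed to an explicit overflow accumulator, so the truncation check
    measures true leaked mass (must be < 1e-12) rather than floating-point
    drift.
    """
    _validate(n, 0, t)
    if truncation < 10 * n:
        raise ValueError(f"truncation must be >= 10 n = {10 * n}, got {truncation}")
    lam, mu = rates.birth_rate, rates.death_rate
    size = truncation + 1
    v = np.zeros(size)
    v[n] = 1.0
    if t == 0.0 or lam + mu == 0.0:
        return v

    Lambda = truncation * (lam + mu)  # uniformization rate (max out-rate)
    ks = np.arange(size, dtype=float)
    stay = 1.0 - ks * (lam + mu) / Lambda
    up = ks * lam / Lambda     # k -> k+1 (top entry leaks to overflow)
    down = ks * mu / Lambda    # k -> k-1

    overflow = 0.0
    remaining = Lambda * t
    chunk_mean = 500.0  # Poisson weights per chunk stay in double range
    while remaining > 0.0:
        m = min(remaining, chunk_mean)
        remaining -= m
        # Poisson(m) weights up to a tail below 1e-16
        kmax = int(m + 10.0 * math.sqrt(m) + 25.0)
        weights = poisson.pmf(np.arange(kmax + 1), m)
        acc = weights[0] * v
        acc_overflow = weights[0] * overflow
        for k in range(1, kmax + 1):
            w = stay * v
            w[1:] += up[:-1] * v[:-1]
            w[:-1] += down[1:] * v[1:]
            overflow = overflow + up[-1] * v[-1]
            v = w
            acc += weights[k] * v
            acc_overflow += weights[k] * overflow
        v = acc
        overflow = acc_overflow
    dist = np.clip(v, 0.0, None)
    if overflow > 1e-12:
        raise TruncationError(
            f"truncation {truncation} loses mass {overflow:.3e} > 1e-12; increase it"
        )
    return dist
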