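"""Sampled-descendant probabilities of a single lineage and the auxiliary q(t).

A lineage alive at time 0 evolves for time t under rates (lambda, mu); each
individual alive at t is then sampled independently with probability rho.
``sampled_count_probability`` gives p_n(t | lambda, mu, rho), the probability
of observing exactly n sampled descendants, with (writing r = lambda - mu
and D(t) = rho lambda + (lambda (1 - rho) - mu) e^{-rt})

    p_0(t) = 1 - rho r / D(t),
    p_1(t) = rho r^2 e^{-rt} / D(t)^2,
    p_n(t) = p_1(t) (lambda q(t))^{n-1},          n > 1,
    q(t)   = rho (1 - e^{-rt}) / D(t),

and the usual lambda = mu limits.  The same quantities rescaled by 1/rho --
the "canonical" forms ptilde_0 = (1 - p_0)/rho, ptilde_1 = p_1/rho,
ptilde_n = p_n/rho, qtilde = q/rho -- depend on the triplet only through

    lambda' = rho lambda,    mu' = mu - lambda (1 - rho),

and are evaluated here directly in (lambda', mu'), with mu' of any sign:

    ptilde_0 = (lambda'-mu') / (lambda' - mu' e^{-(lambda'-mu')t}),
    ptilde_1 = (lambda'-mu')^2 e^{-(lambda'-mu')t} / (lambda' - mu' e^{-(lambda'-mu')t})^2,
    qtilde   = (1 - e^{-(lambda'-mu')t}) / (lambda' - mu' e^{-(lambda'-mu')t}).

The triplet and canonical code paths are deliberately independent so their
numerical agreement is a meaningful cross-check, not a tautology.  All
functions accept scalar or array t; log-scale variants are the
authoritative primitives for the tree densities.
"""

from __future__ import annotations

import numbers

import numpy as np

from .params import BDParams, CanonicalParams

__all__ = [
    "sampled_count_probability",
    "q_function",
    "survival_probability",
    "log_p11",
    "log_survival",
    "log_q",
    "canonical_p0",
    "canonical_p1",
    "canonical_pn",
    "canonical_q",
    "log_canonical_p0",
    "log_canonical_p1",
    "log_canonical_pn",
    "log_canonical_q",
]

# Critical-case switch threshold on |lambda' - mu'| t, relative to
# (1 + lambda' t).  The expm1-based general branch stays accurate far below
# the critical point, so the switch sits near machine precision; the
# critical approximation error it admits, O(1e-13), is negligible against
# every symmetry tolerance (a looser switch would visibly break the swap
# identities for near-critical fits).
_CRITICAL_REL = 1e-13


def _as_time_array(t):
    arr = np.asarray(t, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr < 0.0):
        raise ValueError("t must be finite and >= 0")
    return arr


def _maybe_scalar(value, t):
    if isinstance(t, numbers.Number):
        return float(value)
    return value


# ---------------------------------------------------------------------------
# canonical (lambda', mu') core
# ---------------------------------------------------------------------------

def _canonical_core(t, lp: float, mp: float):
    """(ptilde_0, ptilde_1, qtilde) at times t, elementwise critical switch."""
    t = np.asarray(t, dtype=float)
    u = 1.0 + lp * t
    crit_p0 = 1.0 / u
    crit_p1 = crit_p0 * crit_p0
    crit_q = t / u
    r = lp - mp
    crit_mask = np.abs(r) * t < _CRITICAL_REL * u
    if r == 0.0:
        return crit_p0, crit_p1, crit_q
    if r > 0.0:
        one_minus = -np.expm1(-r * t)            # 1 - e^{-rt}
        x = np.exp(-r * t)
        D = r + mp * one_minus                   # = lambda' - mu' e^{-rt} > 0
        p0 = r / D
        p1 = (r / D) ** 2 * x                    # ratio form: no r^2 underflow
        q = one_minus / D
    else:
        one_minus = -np.expm1(r * t)             # 1 - e^{rt}
        y = np.exp(r * t)
        D = -r + lp * one_minus                  # = mu' - lambda' e^{rt} > 0
        p0 = (-r) * y / D
        p1 = (r / D) ** 2 * y
        q = one_minus / D
    return (
        np.where(crit_mask, crit_p0, p0),
        np.where(crit_mask, crit_p1, p1),
        np.where(crit_mask, crit_q, q),
    )


def _canonical_log_core(t, lp: float, mp: float):
    """(log ptilde_0, log ptilde_1, log qtilde); log qtilde(0) = -inf."""
    t = np.asarray(t, dtype=float)
    u = 1.0 + lp * t
    logu = np.log(u)
    with np.errstate(divide="ignore"):
        crit_lq = np.log(t) - logu
    crit_lp0 = -logu
    crit_lp1 = -2.0 * logu
    r = lp - mp
    crit_mask = np.abs(r) * t < _CRITICAL_REL * u
    if r == 0.0:
        return crit_lp0, crit_lp1, crit_lq
    ar = abs(r)
    if r > 0.0:
        one_minus = -np.expm1(-r * t)
        logD = np.log(r + mp * one_minus)
        lp0 = np.log(ar) - logD
        lp1 = 2.0 * np.log(ar) - r * t - 2.0 * logD
    else:
        one_minus = -np.expm1(r * t)
        logD = np.log(-r + lp * one_minus)
        lp0 = np.log(ar) + r * t - logD
        lp1 = 2.0 * np.log(ar) + r * t - 2.0 * logD
    with np.errstate(divide="ignore"):
        lq = np.log(one_minus) - logD
    return (
        np.where(crit_mask, crit_lp0, lp0),
        np.where(crit_mask, crit_lp1, lp1),
        np.where(crit_mask, crit_lq, lq),
    )


def canonical_p0(t, cp: CanonicalParams):
    """ptilde_0(t | lambda', mu') = (1 - p_0)/rho for any generating triplet."""
    arr = _as_time_array(t)
    return _maybe_scalar(_canonical_core(arr, cp.lambda_prime, cp.mu_prime)[0], t)


def canonical_p1(t, cp: CanonicalParams):
    """ptilde_1(t | lambda', mu') = p_{1,1}(t | lambda, mu, rho)/rho."""
    arr = _as_time_array(t)
    return _maybe_scalar(_canonical_core(arr, cp.lambda_prime, cp.mu_prime)[1], t)


def canonical_q(t, cp: CanonicalParams):
    """qtilde(t | lambda', mu') = q(t | lambda, mu, rho)/rho."""
    arr = _as_time_array(t)
    return _maybe_scalar(_canonical_core(arr, cp.lambda_prime, cp.mu_prime)[2], t)


def canonical_pn(n: int, t, cp: CanonicalParams):
    """ptilde_n = ptilde_1 (lambda' qtilde)^{n-1}, n >= 1."""
    if int(n) != n or n < 1:
        raise ValueError(f"n must be an integer >= 1, got {n}")
    arr = _as_time_array(t)
    _, p1, q = _canonical_core(arr, cp.lambda_prime, cp.mu_prime)
    return _maybe_scalar(p1 * (cp.lambda_prime * q) ** (n - 1), t)


def log_canonical_p0(t, cp: CanonicalParams):
    arr = _as_time_array(t)
    return _maybe_scalar(_canonical_log_core(arr, cp.lambda_prime, cp.mu_prime)[0], t)


def log_canonical_p1(t, cp: CanonicalParams):
    arr = _as_time_array(t)
    return _maybe_scalar(_canonical_log_core(arr, cp.lambda_prime, cp.mu_prime)[1], t)


def log_canonical_q(t, cp: CanonicalParams):
    arr = _as_time_array(t)
    return _maybe_scalar(_canonical_log_core(arr, cp.lambda_prime, cp.mu_prime)[2], t)


def log_canonical_pn(n: int, t, cp: CanonicalParams):
    if int(n) != n or n < 1:
        raise ValueError(f"n must be an integer >= 1, got {n}")
    arr = _as_time_array(t)
    _, lp1, lq = _canonical_log_core(arr, cp.lambda_prime, cp.mu_prime)
    return _maybe_scalar(lp1 + (n - 1) * (np.log(cp.lambda_prime) + lq), t)


# ---------------------------------------------------------------------------
# triplet (lambda, mu, rho) core -- independent stable evaluation
# ---------------------------------------------------------------------------

def _triplet_core(t, lam: float, mu: float, rho: float):
    """(1 - p_0, p_{1,1}, q) at times t from the triplet expressions."""
    t = np.asarray(t, dtype=float)
    u = 1.0 + rho * lam * t
    crit_surv = rho / u
    crit_p11 = rho / (u * u)
    crit_q = rho * t / u
    r = lam - mu
    crit_mask = np.abs(r) * t < _CRITICAL_REL * (1.0 + lam * t)
    if r == 0.0:
        return crit_surv, crit_p11, crit_q
    if r > 0.0:
        one_minus = -np.expm1(-r * t)
        x = np.exp(-r * t)
        D = rho * lam * one_minus + r * x        # = rho lam + (lam(1-rho)-mu) e^{-rt} > 0
        surv = rho * r / D
        p11 = rho * (r / D) ** 2 * x
        q = rho * one_minus / D
    else:
        one_minus = -np.expm1(r * t)             # 1 - e^{rt}
        y = np.exp(r * t)
        D = -r + rho * lam * one_minus           # = (mu - lam(1-rho)) - rho lam e^{rt} ... > 0
        surv = rho * (-r) * y / D
        p11 = rho * (r / D) ** 2 * y
        q = rho * one_minus / D
    return (
        np.where(crit_mask, crit_surv, surv),
        np.where(crit_mask, crit_p11, p11),
        np.where(crit_mask, crit_q, q),
    )


def _triplet_log_core(t, lam: float, mu: float, rho: float):
    t = np.asarray(t, dtype=float)
    logrho = np.log(rho)
    u = 1.0 + rho * lam * t
    logu = np.log(u)
    crit_lsurv = logrho - logu
    crit_lp11 = logrho - 2.0 * logu
    with np.errstate(divide="ignore"):
        crit_lq = logrho + np.log(t) - logu
    r = lam - mu
    crit_mask = np.abs(r) * t < _CRITICAL_REL * (1.0 + lam * t)
    if r == 0.0:
        return crit_lsurv, crit_lp11, crit_lq
    ar = abs(r)
    if r > 0.0:
        one_minus = -np.expm1(-r * t)
        logD = np.log(rho * lam * one_minus + r * np.exp(-r * t))
        lsurv = logrho + np.log(ar) - logD
        lp11 = logrho + 2.0 * np.log(ar) - r * t - 2.0 * logD
    else:
        one_minus = -np.expm1(r * t)
        logD = np.log(-r + rho * lam * one_minus)
        lsurv = logrho + np.log(ar) + r * t - logD
        lp11 = logrho + 2.0 * np.log(ar) + r * t - 2.0 * logD
    with np.errstate(divide="ignore"):
        lq = logrho + np.log(one_minus) - logD
    return (
        np.where(crit_mask, crit_lsurv, lsurv),
        np.where(crit_mask, crit_lp11, lp11),
        np.where(crit_mask, crit_lq, lq),
    )


def survival_probability(t, params: BDParams):
    """1 - p_0(t): probability of at least one sampled descendant."""
    arr = _as_time_array(t)
    surv, _, _ = _triplet_core(arr, params.birth_rate, params.death_rate, params.sampling_prob)
    return _maybe_scalar(surv, t)


def q_function(t, params: BDParams):
    """q(t | lambda, mu, rho); satisfies q(0) = 0 and lambda q(t) < 1."""
    arr = _as_time_array(t)
    _, _, q = _triplet_core(arr, params.birth_rate, params.death_rate, params.sampling_prob)
    return _maybe_scalar(q, t)


def sampled_count_probability(n: int, t, params: BDParams):
    """p_n(t | lambda, mu, rho): exactly n extant-and-sampled descendants."""
    if int(n) != n or n < 0:
        raise ValueError(f"n must be an integer >= 0, got {n}")
    arr = _as_time_array(t)
    surv, p11, q = _triplet_core(arr, params.birth_rate, params.death_rate, params.sampling_prob)
    if n == 0:
        return _maybe_scalar(1.0 - surv, t)
    return _maybe_scalar(p11 * (params.birth_rate * q) ** (n - 1), t)


def log_p11(t, params: BDParams):
    """log p_{1,1}(t), the one-sampled-descendant probability."""
    arr = _as_time_array(t)
    return _maybe_scalar(
        _triplet_log_core(arr, params.birth_rate, params.death_rate, params.sampling_prob)[1], t
    )


def log_survival(t, params: BDParams):
    """log(1 - p_0(t))."""
    arr = _as_time_array(t)
    return _maybe_scalar(
        _triplet_log_core(arr, params.birth_rate, params.death_rate, params.sampling_prob)[0], t
    )


def log_q(t, params: BDParams):
    """log q(t); -inf at t = 0."""
    arr = _as_time_array(t)
    return _maybe_scalar(
        _triplet_log_core(arr, params.birth_rate, params.death_rate, params.sampling_prob)[2], t
    )
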