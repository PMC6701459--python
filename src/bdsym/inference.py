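"""Maximum-likelihood inference in the identifiable (lambda', mu') space.

Conditioned reconstructed-tree likelihoods depend on (lambda, mu, rho) only
through lambda' = rho lambda and mu' = mu - lambda (1 - rho), so the
three-parameter surface carries a perfectly flat one-dimensional ridge.
``fit_canonical_mle`` therefore optimizes over (log lambda', mu') with
lambda' in (0, inf) and mu' unrestricted in sign; ``ridge_profile``
back-transforms the estimate along a rho grid and re-evaluates the triplet
likelihood, exhibiting the ridge and the feasibility boundary; and
``effective_prior_pushforward`` demonstrates how a uniform rho choice on
the feasible interval distorts the induced prior on (lambda, mu, rho) when
the (lambda', mu') prior puts mass on negative mu'.

No model-selection test between rho = 1 and rho < 1 is offered: every
complete-sampling pair lies on a ridge that also contains rho < 1 triplets,
so such a comparison is vacuous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .params import BDParams, CanonicalParams, ConvergenceError, RhoInterval
from .parameter_transform import feasible_rho_interval, from_canonical
from .tree_densities import (
    Conditioning,
    ReconstructedTree,
    tree_log_density,
    tree_log_density_canonical,
)

__all__ = [
    "FitResult",
    "fit_canonical_mle",
    "ridge_profile",
    "PushforwardResult",
    "effective_prior_pushforward",
]

_UNCOND = {Conditioning.UNCOND_STEM, Conditioning.UNCOND_CROWN}


@dataclass(frozen=True)
class FitResult:
    """MLE in canonical coordinates with ridge and feasibility diagnostics."""

    estimate: CanonicalParams
    log_likelihood: float
    converged: bool
    n_evaluations: int
    feasible_rho: RhoInterval
    standard_errors: tuple[float, float] | None
    ridge_degenerate: bool
    message: str = ""


def _negative_log_likelihood(x: np.ndarray, tree, cond) -> float:
    log_lp, mp = x
    if not (-30.0 < log_lp < 30.0) or abs(mp) > 1e6:
        return np.inf
    try:
        ll = tree_log_density_canonical(tree, CanonicalParams(np.exp(log_lp), mp), cond)
    except (ValueError, FloatingPointError):
        return np.inf
    return -ll if np.isfinite(ll) else np.inf


def _hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian of a scalar function of 2 variables."""
    H = np.empty((2, 2))
    steps = h * (1.0 + np.abs(x))
    for i in range(2):
        for j in range(i, 2):
            ei = np.zeros(2)
            ej = np.zeros(2)
            ei[i] = steps[i]
            ej[j] = steps[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * steps[i] * steps[j])
    return H


def fit_canonical_mle(
    tree: ReconstructedTree,
    cond: Conditioning,
    init: CanonicalParams | None = None,
    max_evaluations: int = 2000,
) -> FitResult:
    """Maximize the conditioned tree log-density over (lambda', mu').

    Derivative-free simplex with four starts around a Yule-type guess
    lambda'_0 = max(n-2, 1) / sum(t_i) and mu'_0 = lambda'_0 / 2 (both
    signs of mu'_0, mu' = 0, and mu' near lambda').  A tree with a single
    branching time cannot identify two parameters; such fits are flagged
    ``ridge_degenerate`` (as is any fit with a numerically singular
    curvature) rather than silently returned.
    """
    if cond in _UNCOND:
        raise ValueError(
            "unconditioned rows are not likelihoods for data observed through "
            "sampling; use a conditioned row"
        )
    total_time = sum(tree.branching_times)
    if tree.stem_age is not None:
        total_time += tree.stem_age - (tree.branching_times[0] if tree.n > 1 else 0.0)
    lp0 = max(tree.n - 2, 1) / max(total_time, 1e-9)
    starts = [np.array([np.log(lp0), m]) for m in (0.5 * lp0, -0.5 * lp0, 0.0, 0.9 * lp0)]
    if init is not None:
        starts.insert(0, np.array([np.log(init.lambda_prime), init.mu_prime]))

    nll = lambda x: _negative_log_likelihood(x, tree, cond)
    best = None
    n_eval = 0
    budget = max(max_evaluations // len(starts), 100)
    any_success = False
    for x0 in starts:
        res = minimize(
            nll,
            x0,
            method="Nelder-Mead",
            options={"maxfev": budget, "fatol": 1e-8, "xatol": 1e-8},
        )
        n_eval += res.nfev
        any_success = any_success or bool(res.success)
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None or not np.isfinite(best.fun):
        raise ConvergenceError("no start produced a finite likelihood", best=best)

    x_hat = best.x
    estimate = CanonicalParams(float(np.exp(x_hat[0])), float(x_hat[1]))
    log_lik = -float(best.fun)
    H = _hessian(nll, x_hat)
    eigvals = np.linalg.eigvalsh(H)
    standard_errors = None
    if np.all(eigvals > 0) and np.isfinite(eigvals).all():
        cov = np.linalg.inv(H)
        standard_errors = (float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1])))
    ridge_degenerate = tree.n <= 2 or not np.all(eigvals > 1e-6)
    message = "ridge-degenerate: curvature does not identify both parameters" if ridge_degenerate else ""
    if not any_success and not ridge_degenerate:
        raise ConvergenceError(
            f"simplex did not converge within {max_evaluations} evaluations",
            best=FitResult(
                estimate, log_lik, False, n_eval, feasible_rho_interval(estimate),
                standard_errors, ridge_degenerate, "budget exhausted",
            ),
        )
    return FitResult(
        estimate=estimate,
        log_likelihood=log_lik,
        converged=any_success,
        n_evaluations=n_eval,
        feasible_rho=feasible_rho_interval(estimate),
        standard_errors=standard_errors,
        ridge_degenerate=ridge_degenerate,
        message=message,
    )


def ridge_profile(
    tree: ReconstructedTree,
    cond: Conditioning,
    fit: FitResult,
    rho_grid,
) -> pd.DataFrame:
    """Back-transform the MLE along a rho grid and re-evaluate the likelihood.

    Feasible rows all carry the same log-likelihood (the ridge); rows whose
    rho exceeds the feasible bound are flagged and left unevaluated.
    """
    rows = []
    for rho in np.asarray(rho_grid, dtype=float):
        if fit.feasible_rho.contains(rho):
            p = from_canonical(fit.estimate, float(min(rho, 1.0)))
            rows.append(
                {
                    "rho": float(rho),
                    "birth_rate": p.birth_rate,
                    "death_rate": p.death_rate,
                    "log_likelihood": tree_log_density(tree, p, cond),
                    "feasible": True,
                }
            )
        else:
            rows.append(
                {
                    "rho": float(rho),
                    "birth_rate": np.nan,
                    "death_rate": np.nan,
                    "log_likelihood": np.nan,
                    "feasible": False,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bayesian effective-prior pushforward
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PushforwardResult:
    """Induced (lambda, mu, rho) samples and the count of rejected lambda' draws."""

    samples: pd.DataFrame
    n_rejected: int


def _draw(spec, rng: np.random.Generator, size: int) -> np.ndarray:
    family, *args = spec
    family = family.lower()
    if family == "uniform":
        lo, hi = args
        return rng.uniform(lo, hi, size)
    if family == "exponential":
        (scale,) = args
        return rng.exponential(scale, size)
    if family == "normal":
        loc, scale = args
        return rng.normal(loc, scale, size)
    raise ValueError(f"unsupported prior family {family!r}; use uniform/exponential/normal")


def effective_prior_pushforward(
    prior_lambda_prime,
    prior_mu_prime,
    n_samples: int,
    seed: int,
) -> PushforwardResult:
    """Push a (lambda', mu') prior through a uniform-on-feasible rho choice.

    Draws (lambda', mu') from the given priors (tuples like
    ``("uniform", 0.5, 2.0)``, ``("exponential", scale)`` or
    ``("normal", loc, scale)``), rejecting lambda' <= 0 draws (counted).
    For each pair, rho is drawn uniformly on the feasible interval
    (0, upper]; mass on mu' < 0 shrinks the interval below 1, so the
    induced rho marginal concentrates on small values.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    lam_p = np.empty(0)
    n_rejected = 0
    while lam_p.size < n_samples:
        batch = _draw(prior_lambda_prime, rng, n_samples)
        good = batch[batch > 0.0]
        n_rejected += batch.size - good.size
        lam_p = np.concatenate([lam_p, good])
    lam_p = lam_p[:n_samples]
    mu_p = _draw(prior_mu_prime, rng, n_samples)
    upper = np.where(mu_p >= 0.0, 1.0, 1.0 / (1.0 - mu_p / lam_p))
    rho = rng.uniform(0.0, 1.0, n_samples) * upper
    rho = np.maximum(rho, np.nextafter(0.0, 1.0))
    lam = lam_p / rho
    mu = np.maximum(mu_p - lam_p + lam, 0.0)
    samples = pd.DataFrame(
        {
            "lambda_prime": lam_p,
            "mu_prime": mu_p,
            "rho": rho,
            "birth_rate": lam,
            "death_rate": mu,
        }
    )
    return PushforwardResult(samples=samples, n_rejected=int(n_rejected))
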