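"""Mappings between (lambda, mu, rho) and the canonical pair (lambda', mu').

The forward map is lambda' = rho lambda, mu' = mu - lambda (1 - rho); it
preserves lambda - mu exactly.  Every canonical pair with lambda' > 0 is
realized by a one-parameter family of triplets

    lambda = lambda'/rho,    mu = mu' - lambda' + lambda'/rho,

where rho ranges over (0, 1] when mu' >= 0 and over
(0, 1/(1 - mu'/lambda')] when mu' < 0 (the bound keeps mu >= 0).  All
triplets on this ridge give identical conditioned reconstructed-tree
densities, which is the non-identifiability the inference module respects.
"""

from __future__ import annotations

from .params import BDParams, CanonicalParams, FeasibilityError, Infeasible, RhoInterval

__all__ = [
    "to_canonical",
    "from_canonical",
    "feasible_rho_interval",
    "equivalent_triplet",
    "complete_sampling_equivalent",
]

_BOUND_TOL = 1e-12  # absolute slack so the mu = 0 boundary is accepted


def to_canonical(params: BDParams) -> CanonicalParams:
    """(lambda, mu, rho) -> (lambda' = rho lambda, mu' = mu - lambda (1 - rho))."""
    lam, mu, rho = params.birth_rate, params.death_rate, params.sampling_prob
    if lam <= 0.0:
        raise ValueError("birth_rate must be > 0: no tree-generating process for lambda = 0")
    return CanonicalParams(rho * lam, mu - lam * (1.0 - rho))


def feasible_rho_interval(cp: CanonicalParams) -> RhoInterval:
    """Sampling probabilities for which (lambda', mu') back-transforms to mu >= 0."""
    if cp.mu_prime >= 0.0:
        return RhoInterval(upper=1.0)
    return RhoInterval(upper=min(1.0, 1.0 / (1.0 - cp.mu_prime / cp.lambda_prime)))


def from_canonical(cp: CanonicalParams, rho: float) -> BDParams:
    """Back-transform to the triplet with sampling probability rho.

    Raises :class:`FeasibilityError` when rho lies outside
    :func:`feasible_rho_interval` (the back-transformed mu would be negative).
    """
    interval = feasible_rho_interval(cp)
    if not (0.0 < rho <= 1.0) or not interval.contains(rho, tol=_BOUND_TOL):
        raise FeasibilityError(
            f"rho = {rho} outside the feasible interval (0, {interval.upper}] "
            f"for (lambda' = {cp.lambda_prime}, mu' = {cp.mu_prime})"
        )
    lam = cp.lambda_prime / rho
    mu = cp.mu_prime - cp.lambda_prime + lam
    if abs(mu) < _BOUND_TOL * max(1.0, lam):
        mu = 0.0  # snap float rounding at the mu = 0 feasibility boundary
    if mu < 0.0:  # pragma: no cover - guarded by the interval check
        raise FeasibilityError(f"back-transformed mu = {mu} < 0")
    return BDParams(lam, mu, rho)


def equivalent_triplet(params: BDParams, rho_hat: float) -> BDParams | Infeasible:
    """The triplet with sampling probability rho_hat on the same ridge.

    Feasible exactly when mu/lambda >= 1 (any rho_hat in (0, 1]) or, for
    mu/lambda < 1, when rho_hat <= rho / (1 - mu/lambda).  Returns an
    :class:`Infeasible` value (never raises) otherwise; when feasible the
    conditioned tree density of every tree is identical under both triplets.
    """
    if not (0.0 < rho_hat <= 1.0):
        raise ValueError(f"rho_hat must lie in (0, 1], got {rho_hat}")
    cp = to_canonical(params)
    interval = feasible_rho_interval(cp)
    if not interval.contains(rho_hat, tol=_BOUND_TOL):
        return Infeasible(
            rho_requested=rho_hat,
            upper_bound=interval.upper,
            reason=(
                f"rho_hat = {rho_hat} exceeds the ridge bound {interval.upper} "
                f"(= rho / (1 - mu/lambda)); no non-negative death rate exists"
            ),
        )
    return from_canonical(cp, rho_hat)


def complete_sampling_equivalent(params: BDParams) -> BDParams | Infeasible:
    """The complete-sampling (rho = 1) triplet on the ridge, when it exists.

    Exists iff mu/lambda >= 1 or mu/lambda >= 1 - rho; otherwise the
    equivalent "death rate" mu' is negative and no rho = 1 process matches.
    """
    return equivalent_triplet(params, 1.0)
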