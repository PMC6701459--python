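"""Parameter containers and error types shared across the package.

The sampled linear birth--death process is parameterized either by the
biological triplet (birth rate lambda, death rate mu, present-day sampling
probability rho) or by the identifiable canonical pair

    lambda' = rho * lambda,      mu' = mu - lambda * (1 - rho),

where mu' may be negative.  Conditioned reconstructed-tree densities depend
on the triplet only through (lambda', mu'), which is why the canonical pair
is the natural space for inference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


class FeasibilityError(ValueError):
    """A requested sampling probability lies outside the feasible interval."""


class TruncationError(RuntimeError):
    """The generator-exponential oracle's state-space truncation is too small."""


class UltrametricityError(ValueError):
    """An input tree's tip depths deviate from a common height beyond tolerance."""


class ConvergenceError(RuntimeError):
    """Optimization or a rejection loop exhausted its budget.

    Carries the best-so-far result (if any) in ``best``.
    """

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


def _check_finite_nonneg(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or value < 0.0:
        raise ValueError(f"{name} must be finite and non-negative, got {value}")
    return value


@dataclass(frozen=True)
class RatePair:
    """Per-lineage birth rate (lambda) and death rate (mu), per unit time."""

    birth_rate: float
    death_rate: float

    def __post_init__(self):
        object.__setattr__(self, "birth_rate", _check_finite_nonneg("birth_rate", self.birth_rate))
        object.__setattr__(self, "death_rate", _check_finite_nonneg("death_rate", self.death_rate))

    @property
    def total(self) -> float:
        return self.birth_rate + self.death_rate

    @property
    def growth(self) -> float:
        """Net growth rate r = lambda - mu."""
        return self.birth_rate - self.death_rate

    def swapped(self) -> "RatePair":
        return RatePair(self.death_rate, self.birth_rate)


@dataclass(frozen=True)
class BDParams:
    """Biological parameters (lambda, mu, rho) of the sampled birth--death process."""

    birth_rate: float
    death_rate: float
    sampling_prob: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "birth_rate", _check_finite_nonneg("birth_rate", self.birth_rate))
        object.__setattr__(self, "death_rate", _check_finite_nonneg("death_rate", self.death_rate))
        rho = float(self.sampling_prob)
        if not (0.0 < rho <= 1.0):
            raise ValueError(f"sampling_prob must lie in (0, 1], got {rho}")
        object.__setattr__(self, "sampling_prob", rho)

    @property
    def rates(self) -> RatePair:
        return RatePair(self.birth_rate, self.death_rate)

    @property
    def growth(self) -> float:
        return self.birth_rate - self.death_rate


@dataclass(frozen=True)
class CanonicalParams:
    """The identifiable pair (lambda', mu'); mu' may take any sign.

    lambda' - mu' equals lambda - mu of every generating triplet.
    """

    lambda_prime: float
    mu_prime: float

    def __post_init__(self):
        lp = float(self.lambda_prime)
        mp = float(self.mu_prime)
        if not (math.isfinite(lp) and lp > 0.0):
            raise ValueError(f"lambda_prime must be finite and > 0, got {lp}")
        if not math.isfinite(mp):
            raise ValueError(f"mu_prime must be finite, got {mp}")
        object.__setattr__(self, "lambda_prime", lp)
        object.__setattr__(self, "mu_prime", mp)

    @property
    def growth(self) -> float:
        """lambda' - mu', preserved exactly by the (lambda, mu, rho) mapping."""
        return self.lambda_prime - self.mu_prime

    def swapped(self) -> "CanonicalParams":
        """(mu', lambda'); only well-defined when mu' > 0."""
        if self.mu_prime <= 0.0:
            raise ValueError("swapping requires mu_prime > 0")
        return CanonicalParams(self.mu_prime, self.lambda_prime)


@dataclass(frozen=True)
class RhoInterval:
    """Feasible sampling probabilities (lower, upper]; lower is always 0."""

    upper: float
    lower: float = 0.0

    def __post_init__(self):
        if not (0.0 < self.upper <= 1.0):
            raise ValueError(f"upper must lie in (0, 1], got {self.upper}")
        if self.lower != 0.0:
            raise ValueError("lower bound is always 0 (exclusive)")

    def contains(self, rho: float, tol: float = 1e-12) -> bool:
        return 0.0 < rho <= self.upper + tol


@dataclass(frozen=True)
class Infeasible:
    """A parameter transformation that does not exist.

    Returned (not raised) by the equivalence mappings so grid enumeration
    can record partial feasibility.
    """

    rho_requested: float
    upper_bound: float
    reason: str

    def __bool__(self) -> bool:
        return False
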