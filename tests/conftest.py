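import math

import numpy as np
import pytest

from bdsym import BDParams, CanonicalParams, ReconstructedTree

RATE_GRID = (0.3, 1.0, 2.5)
TIME_GRID = (0.1, 0.5, 1.0, 2.0)


def oracle_truncation(n: int, t: float, lam: float, mu: float) -> int:
    """State-space size for the generator oracle: ~40 geometric tail scales.

    The sampled-lineage offspring law has geometric tail ratio beta with
    1/(1-beta) ~ (lam/r) e^{rt} (supercritical), mu/(mu-lam) (subcritical)
    or 1 + lam t (critical); 40 scales keeps the leaked mass far below the
    oracle's 1e-12 ceiling.
    """
    r = lam - mu
    if abs(r) * t < 1e-9:
        scale = 1.0 + lam * t
    elif r > 0:
        scale = (lam / r) * math.exp(r * t)
    else:
        scale = mu / (-r)
    return max(400, int(40 * n * scale))


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def small_tree():
    """Four tips, branching ages (2, 1.2, 0.3), stem age 2.5."""
    return ReconstructedTree(4, (2.0, 1.2, 0.3), stem_age=2.5)


@pytest.fixture
def two_tip_tree():
    return ReconstructedTree(2, (1.0,), stem_age=2.0)


def random_triplets(rng, count: int):
    lam = rng.uniform(0.05, 3.0, count)
    mu = rng.uniform(0.0, 3.0, count)
    rho = rng.uniform(0.01, 1.0, count)
    return [BDParams(*xs) for xs in zip(lam, mu, rho)]
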