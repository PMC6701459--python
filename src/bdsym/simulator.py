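"""Forward Gillespie simulation of the birth--death process.

Events occur at total rate n (lambda + mu) when n individuals are alive;
each event is a birth with probability p = lambda / (lambda + mu).  The
module simulates population-size trajectories, full genealogies with
rho-sampling at the present and pruning to the reconstructed tree, and a
rejection wrapper for the conditioned tree distributions.  It also exposes
the trajectory probability density L_1(X) and its time reversal, whose
pathwise identity L_1(X | lambda, mu) = L_1(reverse(X) | mu, lambda) is the
mechanism behind the birth--death interchange symmetry.

For the two exactly-n conditionings the branching times are i.i.d. with
density p_{1,1}(t)/q(T) on (0, T); ``sample_branching_times`` draws them
directly by inverting q.  This exact sampler is the practical route for
large tip counts, where the acceptance probability of plain rejection
vanishes; the two samplers are cross-validated in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .params import BDParams, CanonicalParams, ConvergenceError, RatePair
from .tree_densities import Conditioning, ReconstructedTree

__all__ = [
    "BIRTH",
    "DEATH",
    "Trajectory",
    "SimConfig",
    "SimulatedTree",
    "Genealogy",
    "simulate_trajectory",
    "simulate_final_sizes",
    "trajectory_log_density",
    "reverse_trajectory",
    "simulate_genealogy",
    "sample_present",
    "simulate_reconstructed_tree",
    "sample_branching_times",
]

BIRTH = "birth"
DEATH = "death"


@dataclass(frozen=True)
class Trajectory:
    """A population-size path: start count and ordered (time, type) events."""

    t_total: float
    start_count: int
    events: tuple[tuple[float, str], ...]

    def __post_init__(self):
        if self.t_total < 0 or int(self.start_count) != self.start_count or self.start_count < 1:
            raise ValueError("t_total must be >= 0 and start_count a positive integer")
        prev = 0.0
        size = self.start_count
        for time, kind in self.events:
            if not (prev < time < self.t_total):
                raise ValueError("event times must be strictly increasing within (0, t_total)")
            if kind not in (BIRTH, DEATH):
                raise ValueError(f"unknown event type {kind!r}")
            size += 1 if kind == BIRTH else -1
            if size < 0:
                raise ValueError("population size became negative")
            prev = time

    def sizes(self) -> list[int]:
        """Population size immediately before each event."""
        out, size = [], self.start_count
        for _, kind in self.events:
            out.append(size)
            size += 1 if kind == BIRTH else -1
        return out

    @property
    def end_size(self) -> int:
        size = self.start_count
        for _, kind in self.events:
            size += 1 if kind == BIRTH else -1
        return size


def simulate_trajectory(
    rates: RatePair,
    t_total: float,
    start_count: int = 1,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    max_population: int = 1_000_000,
) -> Trajectory:
    """Gillespie simulation of the population-size path up to t_total."""
    if rng is None:
        rng = np.random.default_rng(seed)
    lam, mu = rates.birth_rate, rates.death_rate
    total = lam + mu
    events: list[tuple[float, str]] = []
    size = start_count
    t = 0.0
    while size > 0 and total > 0.0:
        t += rng.exponential(1.0 / (size * total))
        if t >= t_total:
            break
        if rng.random() < lam / total:
            size += 1
            if size > max_population:
                raise OverflowError(
                    f"population exceeded max_population = {max_population}; "
                    "raise the cap explicitly for supercritical long runs"
                )
            events.append((t, BIRTH))
        else:
            size -= 1
            events.append((t, DEATH))
    return Trajectory(t_total=t_total, start_count=start_count, events=tuple(events))


def simulate_final_sizes(
    rates: RatePair,
    t_total: float,
    start_count: int,
    reps: int,
    seed: int,
    max_population: int = 1_000_000,
) -> np.ndarray:
    """Final population sizes of ``reps`` independent trajectories.

    Count-level only (no event log), for distribution checks at scale.
    """
    rng = np.random.default_rng(seed)
    lam, mu = rates.birth_rate, rates.death_rate
    total = lam + mu
    p_birth = lam / total if total > 0 else 0.0
    out = np.empty(reps, dtype=np.int64)
    for i in range(reps):
        size = start_count
        t = 0.0
        while size > 0 and total > 0.0:
            t += rng.exponential(1.0 / (size * total))
            if t >= t_total:
                break
            if rng.random() < p_birth:
                size += 1
                if size > max_population:
                    raise OverflowError("population exceeded max_population")
            else:
                size -= 1
        out[i] = size
    return out


def trajectory_log_density(traj: Trajectory, rates: RatePair) -> float:
    """log L_1(X): event-type factors, waiting times, and the no-event tail.

    Each event with n_i individuals beforehand contributes
    log((lambda+mu) n_i) - (lambda+mu) n_i dt_i plus log p for a birth or
    log(1-p) for a death; the final interval contributes the survival term
    -(lambda+mu) n_end (t_total - t_last).  For an event-free path this is
    -(lambda+mu) start_count t_total.
    """
    lam, mu = rates.birth_rate, rates.death_rate
    total = lam + mu
    if total == 0.0:
        return 0.0
    log_p = math.log(lam / total) if lam > 0 else -math.inf
    log_1mp = math.log(mu / total) if mu > 0 else -math.inf
    logdens = 0.0
    prev = 0.0
    size = traj.start_count
    for time, kind in traj.events:
        if size == 0:
            raise ValueError("event after absorption at size 0")
        logdens += math.log(total * size) - total * size * (time - prev)
        logdens += log_p if kind == BIRTH else log_1mp
        size += 1 if kind == BIRTH else -1
        prev = time
    logdens += -total * size * (traj.t_total - prev)
    return logdens


def reverse_trajectory(traj: Trajectory) -> Trajectory:
    """Time-reverse the path: t -> t_total - t, birth/death labels swapped.

    An involution; the reversed path starts at the original end size.  The
    pathwise identity L_1(X | lambda, mu) = L_1(reverse(X) | mu, lambda)
    holds exactly for paths that return to their start count (the setting
    of the interchange argument); in general the two log-densities differ
    by log(start/end) because the event-rate prefactors read pre-event
    sizes forward and post-event sizes backward.  An absorbed path
    (end size 0) has no valid reversal.
    """
    if traj.end_size == 0:
        raise ValueError("reversal undefined for a path absorbed at size 0")
    events = tuple(
        (traj.t_total - time, DEATH if kind == BIRTH else BIRTH)
        for time, kind in reversed(traj.events)
    )
    return Trajectory(t_total=traj.t_total, start_count=traj.end_size, events=events)


# ---------------------------------------------------------------------------
# genealogies
# ---------------------------------------------------------------------------

@dataclass
class Genealogy:
    """A full simulated genealogy as flat lineage-segment arrays.

    A segment ends either by death, by splitting into two child segments,
    or by reaching the present.  ``extant`` lists segments alive at the end.
    """

    t_total: float
    start_count: int
    parent: list[int]
    child1: list[int]
    child2: list[int]
    t_born: list[float]
    extant: list[int]

    @property
    def n_extant(self) -> int:
        return len(self.extant)


def simulate_genealogy(
    rates: RatePair,
    t_total: float,
    start_count: int = 1,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    max_population: int = 1_000_000,
) -> Genealogy:
    """Gillespie simulation retaining the full genealogy."""
    if rng is None:
        rng = np.random.default_rng(seed)
    lam, mu = rates.birth_rate, rates.death_rate
    total = lam + mu
    parent = [-1] * start_count
    child1 = [-1] * start_count
    child2 = [-1] * start_count
    t_born = [0.0] * start_count
    alive = list(range(start_count))
    t = 0.0
    p_birth = lam / total if total > 0 else 0.0
    while alive and total > 0.0:
        t += rng.exponential(1.0 / (len(alive) * total))
        if t >= t_total:
            break
        i = int(rng.integers(len(alive)))
        node = alive[i]
        if rng.random() < p_birth:
            if len(alive) + 1 > max_population:
                raise OverflowError("population exceeded max_population")
            k = len(parent)
            parent.extend((node, node))
            child1.extend((-1, -1))
            child2.extend((-1, -1))
            t_born.extend((t, t))
            child1[node], child2[node] = k, k + 1
            alive[i] = k
            alive.append(k + 1)
        else:
            alive[i] = alive[-1]
            alive.pop()
    return Genealogy(
        t_total=t_total,
        start_count=start_count,
        parent=parent,
        child1=child1,
        child2=child2,
        t_born=t_born,
        extant=alive,
    )


def sample_present(
    gen: Genealogy,
    rho: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ReconstructedTree | None:
    """Sample extant tips with probability rho and prune to the reconstructed tree.

    Returns ``None`` when no tip is sampled.  For a two-lineage start with
    both initial lineages represented, the crown split is placed at age
    t_total.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if not (0.0 < rho <= 1.0):
        raise ValueError(f"rho must lie in (0, 1], got {rho}")
    n_nodes = len(gen.parent)
    sampled = np.zeros(n_nodes, dtype=bool)
    for idx in gen.extant:
        sampled[idx] = rng.random() < rho
    counts = np.zeros(n_nodes, dtype=np.int64)
    for idx in range(n_nodes - 1, -1, -1):  # children always follow parents
        if gen.child1[idx] == -1:
            counts[idx] = 1 if sampled[idx] else 0
        else:
            counts[idx] = counts[gen.child1[idx]] + counts[gen.child2[idx]]
    n = int(sum(counts[r] for r in range(gen.start_count)))
    if n == 0:
        return None

    taxa = dendropy.TaxonNamespace()
    tip_counter = [0]
    ages: dict[dendropy.Node, float] = {}

    def reduce(idx: int) -> dendropy.Node:
        # skip single-survivor chains iteratively; recursion depth <= n
        while True:
            c1, c2 = gen.child1[idx], gen.child2[idx]
            if c1 == -1:
                tip_counter[0] += 1
                nd = dendropy.Node()
                nd.taxon = taxa.new_taxon(f"T{tip_counter[0]}")
                ages[nd] = 0.0
                return nd
            if counts[c1] > 0 and counts[c2] > 0:
                nd = dendropy.Node()
                ages[nd] = gen.t_total - gen.t_born[c1]
                nd.add_child(reduce(c1))
                nd.add_child(reduce(c2))
                return nd
            idx = c1 if counts[c1] > 0 else c2

    roots = [r for r in range(gen.start_count) if counts[r] > 0]
    if len(roots) == 1:
        root_node = reduce(roots[0])
    elif len(roots) == 2:
        root_node = dendropy.Node()
        ages[root_node] = gen.t_total
        root_node.add_child(reduce(roots[0]))
        root_node.add_child(reduce(roots[1]))
    else:  # pragma: no cover - start_count > 2 unused
        raise ValueError("sample_present supports start counts of 1 or 2")

    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root_node
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            nd.edge.length = ages[nd.parent_node] - ages[nd]
    times = tuple(sorted((ages[nd] for nd in tree.preorder_internal_node_iter()), reverse=True))
    stem_age = gen.t_total if gen.start_count == 1 else None
    if stem_age is not None and n >= 2 and stem_age > times[0]:
        root_node.edge.length = stem_age - times[0]
    if n == 1:
        return ReconstructedTree(1, (), stem_age=gen.t_total if gen.start_count == 1 else None,
                                 topology=tree)
    return ReconstructedTree(n, times, stem_age=stem_age, topology=tree)


# ---------------------------------------------------------------------------
# conditioned simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Configuration of a conditioned reconstructed-tree simulation.

    ``duration`` is the stem age for stem-family conditionings and the
    crown age for crown-family ones; ``n_tips`` is required by the
    exactly-n conditionings.  The seed is mandatory: every attempt of the
    rejection loop runs on its own spawned substream, so accepted replicates
    are reproducible independently of how many rejections preceded them.
    """

    params: BDParams
    conditioning: Conditioning
    duration: float
    seed: int
    n_tips: int | None = None
    max_retries: int = 100_000
    max_population: int = 1_000_000


@dataclass(frozen=True)
class SimulatedTree:
    tree: ReconstructedTree | None
    n_rejected: int

    @property
    def acceptance_rate(self) -> float:
        return 1.0 / (1.0 + self.n_rejected)


_CROWN_CONDS = {Conditioning.CROWN_SURVIVAL, Conditioning.CROWN_AND_N, Conditioning.UNCOND_CROWN}


def simulate_reconstructed_tree(config: SimConfig) -> SimulatedTree:
    """Plain-rejection simulation until the conditioning event holds.

    Supported conditionings: the four survival / exactly-n rows and the two
    unconditioned rows (which accept every outcome, possibly ``None``).
    ``N_UNIFORM_T0`` has no proper simulation target (improper uniform
    origin-age prior) and is rejected.
    """
    cond = config.conditioning
    if cond is Conditioning.N_UNIFORM_T0:
        raise ValueError("N_UNIFORM_T0 has no proper simulation target")
    if cond in (Conditioning.STEM_AND_N, Conditioning.CROWN_AND_N) and not config.n_tips:
        raise ValueError(f"{cond.value} requires n_tips")
    start = 2 if cond in _CROWN_CONDS else 1
    ss = np.random.SeedSequence(config.seed)
    rejections = 0
    for _ in range(config.max_retries):
        rng = np.random.default_rng(ss.spawn(1)[0])
        gen = simulate_genealogy(
            config.params.rates,
            config.duration,
            start_count=start,
            rng=rng,
            max_population=config.max_population,
        )
        tree = sample_present(gen, config.params.sampling_prob, rng=rng)
        if cond in (Conditioning.UNCOND_STEM, Conditioning.UNCOND_CROWN):
            return SimulatedTree(tree, rejections)
        ok = tree is not None
        if ok and start == 2:
            # both initial lineages must be represented: crown split at duration
            ok = tree.n >= 2 and tree.branching_times[0] == config.duration
        if ok and cond is Conditioning.STEM_AND_N:
            ok = tree.n == config.n_tips
        if ok and cond is Conditioning.CROWN_AND_N:
            ok = tree.n == config.n_tips
        if ok:
            return SimulatedTree(tree, rejections)
        rejections += 1
    raise ConvergenceError(
        f"no accepted tree in {config.max_retries} attempts "
        f"(acceptance estimate < {1.0 / config.max_retries:.2e})"
    )


# ---------------------------------------------------------------------------
# exact sampler for the exactly-n conditionings
# ---------------------------------------------------------------------------

def _q_inverse(target: float, cp: CanonicalParams) -> float:
    """Solve qtilde(t) = target for t; target must lie in [0, qtilde(inf))."""
    lp, mp = cp.lambda_prime, cp.mu_prime
    r = lp - mp
    if abs(r) < 1e-12 * max(lp, abs(mp), 1.0):
        return target / (1.0 - target * lp)
    x = (1.0 - target * lp) / (1.0 - target * mp)
    return -math.log(x) / r


def sample_branching_times(
    n: int,
    age: float,
    cp: CanonicalParams,
    cond: Conditioning,
    seed: int,
) -> ReconstructedTree:
    """Draw a tree from an exactly-n conditioned density by inverse transform.

    Under STEM_AND_N (CROWN_AND_N) the n-1 (n-2) branching times are i.i.d.
    on (0, age) with density ptilde_1(t)/qtilde(age), whose CDF is
    qtilde(t)/qtilde(age); ``age`` is the stem (crown) age.  Exact, O(n),
    and free of the rejection bottleneck at large n.
    """
    from .sampled_process import canonical_q  # local import to avoid cycles

    if cond not in (Conditioning.STEM_AND_N, Conditioning.CROWN_AND_N):
        raise ValueError("exact sampling is defined for the exactly-n conditionings only")
    if int(n) != n or n < 2:
        raise ValueError(f"n must be an integer >= 2, got {n}")
    rng = np.random.default_rng(seed)
    k = n - 1 if cond is Conditioning.STEM_AND_N else n - 2
    q_age = canonical_q(age, cp)
    u = rng.uniform(0.0, 1.0, size=k)
    times = np.array([_q_inverse(ui * q_age, cp) for ui in u])
    times = np.clip(times, np.nextafter(0.0, 1.0), np.nextafter(age, 0.0))
    times = np.sort(times)[::-1]
    if cond is Conditioning.STEM_AND_N:
        return ReconstructedTree(n, tuple(times), stem_age=age)
    return ReconstructedTree(n, (age, *times))
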