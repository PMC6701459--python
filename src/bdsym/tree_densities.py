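"""Reconstructed-tree probability densities under seven conditionings.

A reconstructed tree is the ultrametric tree on the sampled extant tips
after pruning extinct and unsampled lineages.  It is summarized by the tip
count n and the branching times t_1 > t_2 > ... > t_{n-1} > 0 measured
backwards from the present, optionally with a stem age t_0 > t_1.

The density of the branching-time vector is a product of the
single-lineage quantities p_{1,1}, 1 - p_0 and q (see
:mod:`bdsym.sampled_process`), one row per conditioning:

    UNCOND_STEM     p_{1,1}(t_0) prod_{i=1}^{n-1} lambda p_{1,1}(t_i)
    UNCOND_CROWN    p_{1,1}(t_1)^2 prod_{i=2}^{n-1} lambda p_{1,1}(t_i)
    STEM_SURVIVAL   p_{1,1}(t_0)/(1-p_0(t_0)) prod_{i=1}^{n-1} lambda p_{1,1}(t_i)
    CROWN_SURVIVAL  [p_{1,1}(t_1)/(1-p_0(t_1))]^2 prod_{i=2}^{n-1} lambda p_{1,1}(t_i)
    N_UNIFORM_T0    n p_{1,1}(t_1)/(1-p_0(t_1)) prod_{i=1}^{n-1} lambda p_{1,1}(t_i)
    STEM_AND_N      prod_{i=1}^{n-1} p_{1,1}(t_i)/q(t_0)
    CROWN_AND_N     1/(n-1) prod_{i=2}^{n-1} p_{1,1}(t_i)/q(t_1)

The same rows evaluated through the canonical functions ptilde_1, ptilde_0,
qtilde and lambda' (with p_{1,1} = rho ptilde_1, 1 - p_0 = rho ptilde_0,
q = rho qtilde) lose every rho factor in the five conditioned rows -- the
conditioned densities depend on (lambda, mu, rho) only through
(lambda', mu').  The two unconditioned rows keep explicit rho factors and
require rho as an extra argument in canonical form.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .params import BDParams, CanonicalParams, UltrametricityError
from .sampled_process import (
    log_canonical_p0,
    log_canonical_p1,
    log_canonical_q,
    log_p11,
    log_q,
    log_survival,
)

__all__ = [
    "Conditioning",
    "ReconstructedTree",
    "read_newick",
    "write_newick",
    "tree_log_density",
    "tree_log_density_canonical",
]


class Conditioning(enum.Enum):
    """The event a reconstructed-tree density is normalized by."""

    UNCOND_STEM = "uncond_stem"
    UNCOND_CROWN = "uncond_crown"
    STEM_SURVIVAL = "stem_survival"
    CROWN_SURVIVAL = "crown_survival"
    N_UNIFORM_T0 = "n_uniform_t0"
    STEM_AND_N = "stem_and_n"
    CROWN_AND_N = "crown_and_n"

    @classmethod
    def parse(cls, label: str) -> "Conditioning":
        try:
            return cls(label.strip().lower())
        except ValueError:
            options = ", ".join(c.value for c in cls)
            raise ValueError(f"unknown conditioning {label!r}; one of: {options}") from None


_STEM_ROWS = {Conditioning.UNCOND_STEM, Conditioning.STEM_SURVIVAL, Conditioning.STEM_AND_N}
_CROWN_ROWS = {
    Conditioning.UNCOND_CROWN,
    Conditioning.CROWN_SURVIVAL,
    Conditioning.CROWN_AND_N,
    Conditioning.N_UNIFORM_T0,
}
_UNCOND_ROWS = {Conditioning.UNCOND_STEM, Conditioning.UNCOND_CROWN}


@dataclass(frozen=True)
class ReconstructedTree:
    """Tip count, ordered branching times (ages), and optional stem age."""

    n: int
    branching_times: tuple[float, ...]
    stem_age: float | None = None
    topology: dendropy.Tree | None = field(default=None, compare=False, repr=False)

    def __post_init__(self):
        if int(self.n) != self.n or self.n < 1:
            raise ValueError(f"n must be an integer >= 1, got {self.n}")
        times = tuple(float(t) for t in self.branching_times)
        if len(times) != self.n - 1:
            raise ValueError(
                f"expected {self.n - 1} branching times for n = {self.n}, got {len(times)}"
            )
        for t in times:
            if not (np.isfinite(t) and t > 0.0):
                raise ValueError(f"branching times must be finite and > 0, got {t}")
        if any(a <= b for a, b in zip(times, times[1:])):
            raise ValueError("branching times must be strictly decreasing")
        if self.stem_age is not None:
            t0 = float(self.stem_age)
            if not np.isfinite(t0) or (times and t0 <= times[0]) or t0 <= 0.0:
                raise ValueError(f"stem_age must exceed the oldest branching time, got {t0}")
            object.__setattr__(self, "stem_age", t0)
        object.__setattr__(self, "branching_times", times)

    @property
    def crown_age(self) -> float:
        if self.n < 2:
            raise ValueError("crown age undefined for a single-tip tree")
        return self.branching_times[0]


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def read_newick(text: str, ultrametric_tol: float = 1e-6) -> ReconstructedTree:
    """Parse a rooted ultrametric Newick string into a :class:`ReconstructedTree`.

    Branch lengths are required; a root edge length, if present, sets the
    stem age.  Tip depths must agree within ``ultrametric_tol`` relative to
    tree height.  Exact branching-time ties are broken downward by one ulp
    with a warning (the densities require strictly decreasing times).
    """
    tree = dendropy.Tree.get(
        data=text,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    root = tree.seed_node
    leaves = tree.leaf_nodes()
    n = len(leaves)

    if n == 1:
        stem = root.edge.length if root is leaves[0] else None
        if stem is None:
            # single tip below a root knee: total path length is the stem age
            stem = 0.0
            nd = leaves[0]
            while nd is not None:
                if nd.edge.length:
                    stem += nd.edge.length
                nd = nd.parent_node
        return ReconstructedTree(1, (), stem_age=stem or None, topology=tree)

    for nd in tree.preorder_node_iter():
        if nd is root:
            continue
        if nd.edge.length is None:
            raise ValueError("all branches must carry lengths")
        if nd.edge.length < 0:
            raise ValueError(f"negative branch length {nd.edge.length}")
    for nd in tree.preorder_internal_node_iter():
        if len(nd.child_nodes()) != 2:
            raise ValueError("tree must be strictly bifurcating")

    depths = {root: 0.0}
    for nd in tree.preorder_node_iter():
        if nd is root:
            continue
        depths[nd] = depths[nd.parent_node] + nd.edge.length
    leaf_depths = np.array([depths[lf] for lf in leaves])
    height = float(leaf_depths.max())
    deviation = float(leaf_depths.max() - leaf_depths.min())
    if deviation > ultrametric_tol * max(height, 1.0):
        raise UltrametricityError(
            f"tree is not ultrametric: max tip-depth deviation {deviation:.3e} "
            f"exceeds tolerance {ultrametric_tol:.1e} x height"
        )

    ages = sorted(
        (height - depths[nd] for nd in tree.preorder_internal_node_iter()), reverse=True
    )
    for i in range(1, len(ages)):
        if ages[i] >= ages[i - 1]:
            warnings.warn(
                "tied branching times; breaking the tie by an infinitesimal jitter",
                stacklevel=2,
            )
            ages[i] = np.nextafter(ages[i - 1], 0.0)

    stem_age = None
    if root.edge.length:
        stem_age = ages[0] + root.edge.length
    return ReconstructedTree(n, tuple(ages), stem_age=stem_age, topology=tree)


def _emit_dendropy(tree: ReconstructedTree) -> str:
    topo = tree.topology
    root = topo.seed_node

    def render(nd) -> str:
        if nd.is_leaf():
            label = nd.taxon.label if nd.taxon is not None else (nd.label or "T")
            label = label.replace(" ", "_")
            s = label
        else:
            s = "(" + ",".join(render(c) for c in nd.child_nodes()) + ")"
        if nd is not root:
            s += f":{nd.edge.length!r}"
        return s

    body = render(root)
    if tree.stem_age is not None and tree.n >= 2:
        root_edge = tree.stem_age - tree.branching_times[0]
        body += f":{root_edge!r}"
    return body + ";"


def write_newick(tree: ReconstructedTree, seed: int = 0) -> str:
    """Serialize to ultrametric Newick; round-trips n, times and stem age.

    When the tree carries no topology, a uniformly random ranked topology
    consistent with the branching times is generated from ``seed`` (under
    the model, ranked topologies are exchangeable given the times).
    """
    if tree.n == 1:
        return f"A:{(tree.stem_age if tree.stem_age is not None else 0.0)!r};"
    if tree.topology is not None:
        return _emit_dendropy(tree)

    rng = np.random.default_rng(seed)
    # coalescent-style construction: merge two random lineages at each age,
    # oldest merge last
    nodes = [(f"T{i + 1}", 0.0) for i in range(tree.n)]
    for age in sorted(tree.branching_times):
        j = rng.integers(len(nodes))
        a = nodes.pop(int(j))
        k = rng.integers(len(nodes))
        b = nodes.pop(int(k))
        label = f"({a[0]}:{(age - a[1])!r},{b[0]}:{(age - b[1])!r})"
        nodes.append((label, age))
    body, age = nodes[0]
    if tree.stem_age is not None:
        body += f":{(tree.stem_age - age)!r}"
    return body + ";"


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------

def _check_requirements(tree: ReconstructedTree, cond: Conditioning) -> None:
    if cond in _STEM_ROWS and tree.stem_age is None:
        raise ValueError(f"{cond.value} requires a stem age")
    if cond in _CROWN_ROWS and tree.n < 2:
        raise ValueError(f"{cond.value} requires n >= 2")


def tree_log_density(tree: ReconstructedTree, params: BDParams, cond: Conditioning) -> float:
    """Log density of the branching times under the triplet parameterization."""
    _check_requirements(tree, cond)
    if params.birth_rate <= 0.0:
        raise ValueError("birth_rate must be > 0 for tree densities")
    times = np.asarray(tree.branching_times, dtype=float)
    log_lam = np.log(params.birth_rate)
    lp11 = log_p11(times, params) if times.size else np.zeros(0)

    if cond is Conditioning.UNCOND_STEM:
        return float(log_p11(tree.stem_age, params) + np.sum(log_lam + lp11))
    if cond is Conditioning.UNCOND_CROWN:
        return float(2.0 * lp11[0] + np.sum(log_lam + lp11[1:]))
    if cond is Conditioning.STEM_SURVIVAL:
        t0 = tree.stem_age
        return float(
            log_p11(t0, params) - log_survival(t0, params) + np.sum(log_lam + lp11)
        )
    if cond is Conditioning.CROWN_SURVIVAL:
        t1 = times[0]
        return float(
            2.0 * (lp11[0] - log_survival(t1, params)) + np.sum(log_lam + lp11[1:])
        )
    if cond is Conditioning.N_UNIFORM_T0:
        t1 = times[0]
        return float(
            np.log(tree.n) + lp11[0] - log_survival(t1, params) + np.sum(log_lam + lp11)
        )
    if cond is Conditioning.STEM_AND_N:
        return float(np.sum(lp11 - log_q(tree.stem_age, params)))
    if cond is Conditioning.CROWN_AND_N:
        t1 = times[0]
        return float(-np.log(tree.n - 1) + np.sum(lp11[1:] - log_q(t1, params)))
    raise ValueError(f"unhandled conditioning {cond}")  # pragma: no cover


def tree_log_density_canonical(
    tree: ReconstructedTree,
    cp: CanonicalParams,
    cond: Conditioning,
    rho: float | None = None,
) -> float:
    """Log density in canonical (lambda', mu') coordinates.

    The five conditioned rows depend on (lambda', mu') only; supplying rho
    for them is rejected (it cannot be inferred from a conditioned tree).
    The two unconditioned rows retain a genuine rho dependence and require
    it.
    """
    _check_requirements(tree, cond)
    if cond in _UNCOND_ROWS:
        if rho is None:
            raise ValueError(f"{cond.value} depends on all three parameters; supply rho")
        if not (0.0 < rho <= 1.0):
            raise ValueError(f"rho must lie in (0, 1], got {rho}")
    elif rho is not None:
        raise ValueError(
            f"{cond.value} is a conditioned density depending only on (lambda', mu'); "
            "rho must not be supplied"
        )
    times = np.asarray(tree.branching_times, dtype=float)
    log_lp = np.log(cp.lambda_prime)
    lp1 = log_canonical_p1(times, cp) if times.size else np.zeros(0)

    if cond is Conditioning.UNCOND_STEM:
        return float(
            np.log(rho) + log_canonical_p1(tree.stem_age, cp) + np.sum(log_lp + lp1)
        )
    if cond is Conditioning.UNCOND_CROWN:
        return float(2.0 * (np.log(rho) + lp1[0]) + np.sum(log_lp + lp1[1:]))
    if cond is Conditioning.STEM_SURVIVAL:
        t0 = tree.stem_age
        return float(
            log_canonical_p1(t0, cp) - log_canonical_p0(t0, cp) + np.sum(log_lp + lp1)
        )
    if cond is Conditioning.CROWN_SURVIVAL:
        t1 = times[0]
        return float(
            2.0 * (lp1[0] - log_canonical_p0(t1, cp)) + np.sum(log_lp + lp1[1:])
        )
    if cond is Conditioning.N_UNIFORM_T0:
        t1 = times[0]
        return float(
            np.log(tree.n) + lp1[0] - log_canonical_p0(t1, cp) + np.sum(log_lp + lp1)
        )
    if cond is Conditioning.STEM_AND_N:
        return float(np.sum(lp1 - log_canonical_q(tree.stem_age, cp)))
    if cond is Conditioning.CROWN_AND_N:
        t1 = times[0]
        return float(-np.log(tree.n - 1) + np.sum(lp1[1:] - log_canonical_q(t1, cp)))
    raise ValueError(f"unhandled conditioning {cond}")  # pragma: no cover
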