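# Methods

## Model

A linear birth–death process starts from one lineage (stem) or two
lineages (crown); each lineage independently splits at rate λ ≥ 0 and dies
at rate μ ≥ 0, both constant through time. At the present, each surviving
individual is sampled independently with probability ρ ∈ (0, 1]. The
*reconstructed tree* keeps only lineages with sampled descent; it is
summarized by its tip count n and branching ages t₁ > … > t_{n−1} > 0
(time before present), optionally with a stem age t₀ > t₁. Assumptions:
rates identical across lineages and constant in time, sampling independent
and homogeneous across tips, no serial (through-time) sampling.

## Core quantities

Single-lineage transition probabilities use the classical geometric law
p₁,₀ = α, p₁,ₘ = (1−α)(1−β)β^{m−1} with
α = μ(e^{rt}−1)/(λe^{rt}−μ), β = λ(e^{rt}−1)/(λe^{rt}−μ), r = λ−μ, and the
n-lineage law by the standard n-fold composition. The sampled-descendant
law p_n(t | λ, μ, ρ) and the auxiliary q(t) (with p_n = p₁,₁ (λq)^{n−1})
are evaluated directly from the incomplete-sampling expressions; their
1/ρ-rescaled canonical forms p̃₀, p̃₁, p̃_n, q̃ are evaluated from a second,
independent code path written purely in (λ′, μ′) = (ρλ, μ − λ(1−ρ)).
Keeping the two paths independent makes their numerical agreement in the
tree densities a genuine cross-check of the reparameterization rather
than a tautology. μ′ < 0 is a first-class input throughout; the swap
identities (exchanging λ′ and μ′) are only asserted for μ′ > 0, where the
swap is well defined.

## Numerical choices

- All exponentials go through `expm1`-based forms arranged so every
  denominator is a sum of same-sign terms; survival factors like 1−β are
  computed in closed form (r e^{−rt}/denominator), not by subtraction —
  at rates ~100 the naive 1−β underflows to 0 and would make the
  interchange-symmetry check vacuously true.
- The critical case λ = μ uses the limit forms (α = β = λt/(1+λt) etc.).
  The switch triggers when |λ−μ|·t < 1e−13·(1+λt): the general branch is
  stable essentially to machine precision, and a looser switch would
  inject approximation error of its own order into near-critical fits,
  visibly breaking the 1e−10 swap-symmetry checks. Natural-scale forms use
  (r/denominator)² ratios so tiny r cannot underflow.
- Log-scale variants of all probability functions are the authoritative
  primitives for tree densities, which would otherwise underflow at large
  n.
- The independent transition oracle evaluates exp(tQ)·e_n for the
  truncated generator by uniformization (chunked Poisson-weighted powers
  of P = I + Q/Λ, chunk mean 500). Births out of the top state go to an
  explicit overflow accumulator, so the truncation check bounds true
  leaked mass (< 1e−12) instead of conflating it with rounding drift.
- Feasibility boundaries: ρ-interval membership uses absolute tolerance
  1e−12, and a back-transformed |μ| < 1e−12·max(1, λ) is snapped to
  exactly 0, so the μ = 0 boundary point is representable.
- Newick I/O (via dendropy) requires bifurcating trees with branch
  lengths; ultrametricity tolerance is 1e−6 relative to tree height
  (overridable). Tied branching ages are broken downward by one ulp with
  a warning, since the densities need strictly decreasing times.

## Tree densities

Seven conditionings are implemented: unconditioned stem/crown,
survival-conditioned stem/crown, exactly-n stem/crown, and
n-with-uniform-origin-age. Each is a product of p₁,₁, 1−p₀ and q factors
over the branching ages, with the printed combinatorial constants
(n, 1/(n−1)) and no additional labeled-topology factors; densities are
over ordered branching-age vectors. Crown-family rows evaluate all their
ratio factors at the crown age t₁ (the analog of t₀ in the stem rows);
under this reading the two-tip uniform-origin density integrates to
exactly 1 and ∫₀^{t₀} p₁,₁ = q(t₀), both verified by quadrature in the
suite. The five conditioned rows accept only (λ′, μ′); passing ρ to them
is an error, which guards against reading a sampling probability off a
likelihood that cannot identify one. The two unconditioned rows require
ρ explicitly.

## Simulation

The forward simulator is plain Gillespie: waiting times exponential at
rate n(λ+μ), births with probability λ/(λ+μ). Genealogies are kept as flat
lineage-segment arrays; ρ-sampling marks extant tips and a single reverse
pass counts sampled descendants, after which pruning suppresses
single-survivor chains iteratively. Conditioned trees come from plain
rejection (survival, both-crown-lineages-survive, or exact tip count),
with each attempt on its own spawned substream of the mandatory seed so
accepted replicates are reproducible regardless of the rejection count;
the rejection count and an acceptance-rate estimate are reported.
A population cap (default 10⁶) guards supercritical runs.

For the exactly-n conditionings the branching ages are i.i.d. with density
p̃₁(t)/q̃(T) on (0, T), so `sample_branching_times` draws them exactly by
inverting q̃ (a closed-form one-line inverse). This exact sampler is the
practical route to large-n studies — the acceptance probability of hitting
an exact tip count of 200 by rejection is a fraction of a percent at a
population of hundreds, which is out of reach for a study of hundreds of
replicates — and it is cross-validated against the rejection simulator by
a chi-square/KS comparison at n = 2.

Trajectory densities L₁(X) multiply event-type factors p^k(1−p)^k, the
waiting-time terms, and the terminal no-event factor. The time-reversal
identity L₁(X | λ, μ) = L₁(reverse(X) | μ, λ) is exact for paths returning
to their start count; in general the two differ by log(start/end), and
reversal of a path absorbed at 0 is undefined — both facts are enforced
and documented in the API.

## Inference

`fit_canonical_mle` maximizes a conditioned tree log-density over
(log λ′, μ′) ∈ ℝ², Nelder–Mead with four starts around the Yule-type
guess λ′₀ = max(n−2, 1)/Σtᵢ (μ′ starts at ±λ′₀/2, 0 and 0.9λ′₀),
log-likelihood tolerance 1e−8, evaluation budget 2000. Unconditioned rows
are rejected: they are not likelihoods for data observed through
sampling. Standard errors come from a central finite-difference Hessian
in (log λ′, μ′) and are reported only when it is definite; trees with
n ≤ 2 or numerically singular curvature are flagged `ridge_degenerate`
rather than returned silently — one branching time cannot identify two
parameters. For exactly-n conditionings the likelihood is symmetric under
swapping λ′ and μ′ (for μ′ > 0): both orderings attain the maximum, so
which rate is "birth" must be asserted a priori, not estimated.

`ridge_profile` back-transforms the estimate along a ρ grid and
re-evaluates the triplet likelihood: feasible rows are constant to
rounding (the ridge), rows beyond 1/(1−μ′/λ′) are flagged infeasible. No
ρ = 1 vs ρ < 1 model-selection statistic is offered, because equality
along the ridge makes any such comparison carry zero information; the
profile itself is the demonstration.

`effective_prior_pushforward` draws (λ′, μ′) from user priors (uniform,
exponential or normal families), draws ρ uniformly on the feasible
interval, and back-transforms. With μ′ ≥ 0 priors the induced ρ marginal
is exactly uniform; any prior mass on μ′ < 0 shrinks feasible intervals
below 1 and skews ρ toward small values — the distortion a Bayesian
analysis must account for when parameterizing by (λ′, μ′).

## Synthetic data and study sizes

There are no external datasets; every test input is a hand-written Newick
fixture or a simulator draw. The fixture generator emulates a
moderately supercritical, incompletely sampled clade (λ = 1, μ = 0.5,
ρ = 0.8, age 3) — rate ratios and sampling fractions typical of
macroevolutionary applications. The parameter-recovery study uses 200-tip
trees under the exactly-n crown conditioning at (λ′, μ′) = (1.0, 0.5),
with the crown age drawn uniformly from (8.5, 9.5) per replicate — the age
window where such a process expects on the order of 200 sampled tips, so
the conditioning is not extreme; because the likelihood conditions on the
crown age, any crown-age law gives a valid consistency check. The test
suite runs 200 replicates; the acceptance script reports medians and RMSE
over 100. Monte-Carlo distribution checks use 10⁵ replicates in the test
suite (4 binomial standard errors) and 2×10⁴ in the acceptance script.

What passing these checks shows — and does not. The simulator-vs-formula
and recovery checks validate internal consistency of model, sampler and
optimizer under the model's own assumptions (constant rates, homogeneous
sampling, ultrametric error-free trees). They say nothing about
rate-variation, diversified or serial sampling, or phylogenetic-error
robustness on real data, all of which are out of scope.

## Known limitations

- Serial/through-time sampling, time-varying or lineage-specific rates,
  and multi-type processes are not modeled.
- The uniform-origin-age conditioning has no proper simulation target
  (the origin prior is improper), so the simulator rejects it; its density
  is still evaluated and normalization-checked.
- Rejection simulation of exact tip counts is practical only for small n;
  large-n studies should use the exact conditioned sampler.
- MLE standard errors are curvature-based; no bootstrap intervals.
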