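# bdsym

Constant-rate birth–death phylodynamics with incomplete present-day
sampling: interchange symmetries, the identifiable two-parameter
reparameterization, reconstructed-tree probability densities, forward
simulation, and maximum-likelihood inference that respects the
non-identifiability of (λ, μ, ρ).

## The problem

Linear birth–death models are the standard generative prior for dated
phylogenies: each lineage speciates (or transmits) at rate λ and goes
extinct (or is removed) at rate μ, and each individual alive at the
present is sampled independently with probability ρ. Biologists fit these
models to *reconstructed trees* — the ultrametric trees left after pruning
extinct and unsampled lineages — to estimate diversification or epidemic
parameters.

Two structural facts make naive fitting of (λ, μ, ρ) treacherous, and this
package implements both:

1. **Interchange symmetry.** The scaled transition probabilities
   λⁿ μᵐ p<sub>n,m</sub>(t | λ, μ) are invariant under swapping λ and μ; in
   particular p₁,₁(t | λ, μ) = p₁,₁(t | μ, λ). The mechanism is pathwise:
   the density of any population trajectory that returns to its starting
   size equals the density of its time reversal with the rates
   interchanged.
2. **Non-identifiability under incomplete sampling.** Every conditioned
   reconstructed-tree density depends on (λ, μ, ρ) only through

       λ′ = ρλ,    μ′ = μ − λ(1 − ρ),

   so the three-parameter likelihood surface carries a perfectly flat
   one-dimensional ridge and only (λ′, μ′) can be estimated. The canonical
   "death rate" μ′ may be **negative**, in which case the pair has no
   complete-sampling interpretation and only sampling probabilities
   ρ ∈ (0, 1/(1 − μ′/λ′)] back-transform to a valid (λ, μ ≥ 0, ρ) triplet.

The library provides the classical transition probabilities with a
generator-exponential oracle, the sampled-descendant law p_n(t | λ, μ, ρ)
and its canonical forms, the (λ, μ, ρ) ↔ (λ′, μ′) mappings with exact
feasibility intervals, seven reconstructed-tree log-densities (stem/crown
origin; unconditioned, survival-conditioned, exactly-n-conditioned, and
uniform-origin-age), a Gillespie simulator with ρ-sampling and pruning,
MLE over (log λ′, μ′), ridge diagnostics, and the Bayesian effective-prior
pushforward that shows how a "uniform" ρ choice skews toward small ρ.

## Worked example

The paper-level headline in code — a fast-growing, half-sampled process has
a *negative* canonical death rate:

```python
>>> from bdsym import BDParams, to_canonical, feasible_rho_interval
>>> cp = to_canonical(BDParams(birth_rate=4.0, death_rate=1.0, sampling_prob=0.5))
>>> cp
CanonicalParams(lambda_prime=2.0, mu_prime=-1.0)
>>> feasible_rho_interval(cp).upper
0.6666666666666666
```

μ′ = −μ here, and only ρ ≤ 2/3 maps this pair back to a non-negative death
rate. Fitting a 200-tip tree simulated at (λ′ = 1.0, μ′ = 0.5) with crown
age 9 and conditioning on the tip count:

```python
>>> import numpy as np
>>> from bdsym import (CanonicalParams, Conditioning, fit_canonical_mle,
...                    ridge_profile, sample_branching_times)
>>> tree = sample_branching_times(200, 9.0, CanonicalParams(1.0, 0.5),
...                               Conditioning.CROWN_AND_N, seed=42)
>>> fit = fit_canonical_mle(tree, Conditioning.CROWN_AND_N)
>>> fit.estimate
CanonicalParams(lambda_prime=0.9387869255715282, mu_prime=0.2798300003637265)
>>> ridge_profile(tree, Conditioning.CROWN_AND_N, fit, np.linspace(0.2, 1.0, 5))
   rho  birth_rate  death_rate  log_likelihood  feasible
0  0.2    4.693935    4.034978     -246.248776      True
1  0.4    2.346967    1.688010     -246.248776      True
2  0.6    1.564645    0.905688     -246.248776      True
3  0.8    1.173484    0.514527     -246.248776      True
4  1.0    0.938787    0.279830     -246.248776      True
```

The estimate lands near the truth (standard errors ≈ 0.14 on log λ′ and
0.21 on μ′), and the profile makes the ridge explicit: every sampling
probability on the feasible interval back-transforms to a triplet with the
*identical* log-likelihood, so the data cannot distinguish a
densely-sampled slow process from a sparsely-sampled fast one — and a
"test" of ρ = 1 against ρ < 1 is meaningless.

The same operations are available from the shell:

```bash
bdsym transform --lambda 4 --mu 1 --rho 0.5 --json
bdsym simulate --lambda 1 --mu 0.3 --rho 1 --t0 4 --conditioning stem_and_n \
    --n 8 --reps 5 --seed 5 --out trees.nwk
bdsym fit --tree trees.nwk --conditioning stem_and_n --json
bdsym verify --symmetry transition
```

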