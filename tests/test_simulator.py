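"""Unit tests for the Gillespie simulator, trajectory density, and pruning."""

import math

import numpy as np
import pytest
from scipy import stats

from bdsym import (
    BDParams,
    Conditioning,
    ConvergenceError,
    ReconstructedTree,
    SimConfig,
    Trajectory,
    q_function,
    reverse_trajectory,
    sample_branching_times,
    sample_present,
    sampled_count_probability,
    simulate_genealogy,
    simulate_reconstructed_tree,
    simulate_trajectory,
    to_canonical,
    trajectory_log_density,
    transition_probability,
)
from bdsym.params import RatePair
from bdsym.simulator import BIRTH, DEATH, simulate_final_sizes


class TestTrajectories:
    def test_validation(self):
        with pytest.raises(ValueError):
            Trajectory(1.0, 1, ((0.5, DEATH), (0.7, DEATH)))  # size would go negative
        with pytest.raises(ValueError):
            Trajectory(1.0, 1, ((0.7, BIRTH), (0.5, BIRTH)))  # out of order
        with pytest.raises(ValueError):
            Trajectory(1.0, 1, ((1.5, BIRTH),))               # beyond t_total

    def test_sizes_and_end_size(self):
        traj = Trajectory(2.0, 1, ((0.3, BIRTH), (0.9, BIRTH), (1.4, DEATH)))
        assert traj.sizes() == [1, 2, 3]
        assert traj.end_size == 2

    def test_event_free_log_density(self):
        traj = Trajectory(1.0, 1, ())
        assert trajectory_log_density(traj, RatePair(1.0, 1.0)) == pytest.approx(-2.0)

    def test_reversal_identity_on_return_paths(self):
        # L1(X | lam, mu) == L1(reverse(X) | mu, lam) for paths with
        # end size == start size -- the interchange mechanism, pathwise
        rates = RatePair(1.0, 0.8)
        checked = 0
        seed = 0
        while checked < 100:
            seed += 1
            traj = simulate_trajectory(rates, 1.5, seed=seed)
            if traj.end_size != traj.start_count:
                continue
            forward = trajectory_log_density(traj, rates)
            backward = trajectory_log_density(reverse_trajectory(traj), rates.swapped())
            assert forward == pytest.approx(backward, abs=1e-12)
            checked += 1

    def test_reversal_is_involution(self):
        for seed in range(30):
            traj = simulate_trajectory(RatePair(1.0, 0.6), 2.0, seed=seed)
            if traj.end_size == 0:
                continue
            back = reverse_trajectory(reverse_trajectory(traj))
            assert back.start_count == traj.start_count
            assert [k for _, k in back.events] == [k for _, k in traj.events]
            # times reproduce up to the float rounding of t -> T - t twice
            assert [t for t, _ in back.events] == pytest.approx(
                [t for t, _ in traj.events], abs=1e-15
            )

    def test_reversal_swaps_event_labels(self):
        traj = Trajectory(1.0, 1, ((0.25, BIRTH), (0.75, DEATH)))
        rev = reverse_trajectory(traj)
        assert rev.events == ((0.25, BIRTH), (0.75, DEATH))  # mirrored and relabeled
        assert rev.start_count == 1

    def test_absorbed_paths_cannot_be_reversed(self):
        traj = Trajectory(1.0, 1, ((0.4, DEATH),))
        with pytest.raises(ValueError):
            reverse_trajectory(traj)

    def test_reproducibility(self):
        a = simulate_trajectory(RatePair(1.0, 0.5), 2.0, seed=99)
        b = simulate_trajectory(RatePair(1.0, 0.5), 2.0, seed=99)
        assert a == b

    def test_pure_death_goes_extinct(self):
        traj = simulate_trajectory(RatePair(0.0, 1.0), 10.0, start_count=3, seed=0)
        assert traj.end_size == 0

    def test_population_cap(self):
        with pytest.raises(OverflowError):
            simulate_trajectory(RatePair(5.0, 0.0), 10.0, seed=1, max_population=50)


class TestDistributionalAgreement:
    def test_pure_birth_no_event_probability(self):
        sizes = simulate_final_sizes(RatePair(1.0, 0.0), 1.0, 1, 20000, seed=5)
        frac = (sizes == 1).mean()
        se = math.sqrt(math.exp(-1.0) * (1 - math.exp(-1.0)) / 20000)
        assert abs(frac - math.exp(-1.0)) < 4 * se

    def test_final_size_distribution_matches_closed_form(self):
        rates = RatePair(1.0, 0.5)
        reps = 20000
        sizes = simulate_final_sizes(rates, 1.0, 1, reps, seed=7)
        for m in range(6):
            p = transition_probability(1, m, 1.0, rates)
            se = math.sqrt(p * (1 - p) / reps)
            assert abs((sizes == m).mean() - p) < 4 * se

    def test_sampled_tip_counts_match_critical_branch(self):
        # rho-thinned extant counts against the critical-case formulas
        params = BDParams(1.0, 1.0, 0.8)
        reps = 20000
        sizes = simulate_final_sizes(params.rates, 1.0, 1, reps, seed=11)
        counts = np.random.default_rng(12).binomial(sizes, params.sampling_prob)
        for n in range(6):
            p = sampled_count_probability(n, 1.0, params)
            se = math.sqrt(p * (1 - p) / reps)
            assert abs((counts == n).mean() - p) < 4 * se


class TestGenealogyAndPruning:
    def test_complete_sampling_keeps_all_extant(self):
        gen = simulate_genealogy(RatePair(1.0, 0.3), 2.0, seed=21)
        tree = sample_present(gen, 1.0, seed=1)
        if gen.n_extant == 0:
            assert tree is None
        else:
            assert tree.n == gen.n_extant

    def test_tiny_rho_usually_empty(self):
        none_count = 0
        for seed in range(30):
            gen = simulate_genealogy(RatePair(1.0, 0.5), 1.0, seed=seed)
            if sample_present(gen, 1e-6, seed=seed) is None:
                none_count += 1
        assert none_count == 30

    def test_reconstructed_tree_is_consistent(self):
        gen = simulate_genealogy(RatePair(1.5, 0.3), 2.5, seed=33)
        tree = sample_present(gen, 0.7, seed=4)
        assert tree is not None
        if tree.n >= 2:
            assert len(tree.branching_times) == tree.n - 1
            assert tree.stem_age == 2.5
            assert all(t < 2.5 for t in tree.branching_times)


class TestConditionedSimulation:
    def test_exact_n_conditioning(self):
        cfg = SimConfig(
            params=BDParams(1.0, 0.5, 0.8),
            conditioning=Conditioning.STEM_AND_N,
            duration=2.0,
            n_tips=3,
            seed=17,
        )
        result = simulate_reconstructed_tree(cfg)
        assert result.tree.n == 3
        assert result.tree.stem_age == 2.0
        assert result.n_rejected >= 0

    def test_crown_first_split_at_crown_age(self):
        cfg = SimConfig(
            params=BDParams(1.0, 0.5, 0.9),
            conditioning=Conditioning.CROWN_SURVIVAL,
            duration=2.5,
            seed=23,
        )
        result = simulate_reconstructed_tree(cfg)
        assert result.tree.branching_times[0] == 2.5
        assert result.tree.stem_age is None

    def test_deterministic_given_seed(self):
        cfg = SimConfig(
            params=BDParams(1.0, 0.5, 1.0),
            conditioning=Conditioning.STEM_AND_N,
            duration=2.0,
            n_tips=2,
            seed=29,
        )
        a = simulate_reconstructed_tree(cfg)
        b = simulate_reconstructed_tree(cfg)
        assert a.tree.branching_times == b.tree.branching_times
        assert a.n_rejected == b.n_rejected

    def test_retry_exhaustion_raises(self):
        cfg = SimConfig(
            params=BDParams(0.1, 2.0, 0.5),
            conditioning=Conditioning.STEM_AND_N,
            duration=5.0,
            n_tips=40,  # essentially impossible under these rates
            seed=31,
            max_retries=50,
        )
        with pytest.raises(ConvergenceError):
            simulate_reconstructed_tree(cfg)

    def test_uniform_origin_row_not_simulable(self):
        cfg = SimConfig(
            params=BDParams(1.0, 0.5, 1.0),
            conditioning=Conditioning.N_UNIFORM_T0,
            duration=2.0,
            seed=1,
        )
        with pytest.raises(ValueError):
            simulate_reconstructed_tree(cfg)

    def test_branching_times_match_density(self):
        # the accepted two-tip stem trees carry a branching time with CDF
        # q(t)/q(t0); chi-square against the closed form at the 1% level
        params = BDParams(1.0, 0.5, 1.0)
        t0 = 2.0
        reps = 10000
        times = np.empty(reps)
        for i in range(reps):
            result = simulate_reconstructed_tree(
                SimConfig(
                    params=params,
                    conditioning=Conditioning.STEM_AND_N,
                    duration=t0,
                    n_tips=2,
                    seed=700_000 + i,
                )
            )
            times[i] = result.tree.branching_times[0]
        edges = np.linspace(0.0, t0, 11)
        cdf = np.array([q_function(e, params) for e in edges]) / q_function(t0, params)
        expected = np.diff(cdf) * reps
        observed, _ = np.histogram(times, bins=edges)
        chi2 = ((observed - expected) ** 2 / expected).sum()
        assert 1.0 - stats.chi2.cdf(chi2, len(expected) - 1) > 0.01


class TestExactSampler:
    def test_matches_rejection_sampler_distribution(self):
        # dual route: inverse-CDF sampler vs Gillespie rejection, same law
        params = BDParams(1.0, 0.5, 1.0)
        cp = to_canonical(params)
        t0 = 2.0
        exact = np.array(
            [
                sample_branching_times(2, t0, cp, Conditioning.STEM_AND_N, seed=i)
                .branching_times[0]
                for i in range(4000)
            ]
        )
        u = np.array([q_function(t, params) for t in exact]) / q_function(t0, params)
        assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_crown_layout(self):
        tree = sample_branching_times(
            6, 3.0, to_canonical(BDParams(1.0, 0.5, 0.8)), Conditioning.CROWN_AND_N, seed=2
        )
        assert tree.n == 6
        assert tree.branching_times[0] == 3.0
        assert tree.stem_age is None

    def test_only_exact_n_rows_supported(self):
        with pytest.raises(ValueError):
            sample_branching_times(
                4, 2.0, to_canonical(BDParams(1, 0.5, 1)), Conditioning.STEM_SURVIVAL, seed=0
            )
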