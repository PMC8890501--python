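"""Wright-Fisher dynamics: invariants, fixation against a Markov oracle,
start-genotype choice, logistic fits and the G50 statistic."""

import numpy as np
import pandas as pd
import pytest

from ribolandscape import build_library
from ribolandscape.evolution import (
    ExtinctionError,
    SimConfig,
    batch_simulate,
    choose_start,
    fit_logistic,
    g50,
    logistic_curve,
    run_simulation,
)
from ribolandscape.fitness import FitnessLandscape
from ribolandscape.genotypes import distances_to


def flat_fitness(spec, value=1.0):
    return pd.Series(value, index=build_library(spec), dtype=float)


def wf_fixation_probability(n, fit_a, fit_b, start_a):
    """Transition-matrix oracle: P(type A fixes) in a 2-type WF chain."""
    states = np.arange(n + 1)
    T = np.zeros((n + 1, n + 1))
    for i in states:
        p = (fit_a * i) / (fit_a * i + fit_b * (n - i)) if i > 0 else 0.0
        from scipy.stats import binom

        T[i] = binom.pmf(states, n, p)
    dist = np.zeros(n + 1)
    dist[start_a] = 1.0
    for _ in range(2000):
        dist = dist @ T
    return dist[n]


class TestRunSimulation:
    def test_no_mutation_stays_monomorphic(self, toy_spec2, rng):
        fitness = flat_fitness(toy_spec2)
        fitness.loc["AC"] = 0.7
        traj, pop = run_simulation(
            fitness, toy_spec2, "AC", 50, 0.0, 30, rng, return_population=True
        )
        assert pop == {"AC": 50}
        np.testing.assert_allclose(traj, 0.7)

    def test_flat_landscape_mean_fitness_stays_one(self, toy_spec2, rng):
        traj = run_simulation(
            flat_fitness(toy_spec2), toy_spec2, "AA", 100, 0.05, 50, rng
        )
        np.testing.assert_allclose(traj, 1.0)

    def test_population_size_constant(self, toy_spec2, rng):
        fitness = pd.Series(
            rng.uniform(0.1, 2.0, toy_spec2.library_size),
            index=build_library(toy_spec2),
        )
        _, pop = run_simulation(
            fitness, toy_spec2, "AA", 64, 0.1, 40, rng, return_population=True
        )
        assert sum(pop.values()) == 64

    def test_trajectory_length_includes_generation_zero(self, toy_spec2, rng):
        traj = run_simulation(
            flat_fitness(toy_spec2), toy_spec2, "AA", 10, 0.0, 25, rng
        )
        assert traj.shape == (26,)

    def test_zero_fitness_start_raises_extinction(self, toy_spec2, rng):
        fitness = flat_fitness(toy_spec2)
        fitness.loc["AA"] = 0.0
        with pytest.raises(ExtinctionError) as err:
            run_simulation(fitness, toy_spec2, "AA", 20, 0.0, 10, rng)
        assert err.value.generation == 1

    def test_missing_fitness_treated_as_zero(self, toy_spec2, rng):
        fitness = flat_fitness(toy_spec2)
        fitness.loc["AC"] = np.nan
        traj = run_simulation(fitness, toy_spec2, "AA", 50, 0.0, 10, rng)
        np.testing.assert_allclose(traj, 1.0)


class TestFixation:
    def test_fixation_matches_markov_chain_oracle(self, toy_spec1):
        """N=10 two-genotype chain, selection 2:1, mu=0, 2000 replicates."""
        n, reps = 10, 2000
        fitness = pd.Series(
            {"A": 2.0, "C": 1.0, "G": 0.0, "U": 0.0}
        ).reindex(build_library(toy_spec1))
        expected = wf_fixation_probability(n, 2.0, 1.0, start_a=5)
        master = np.random.SeedSequence(77)
        fixed = 0
        for child in master.spawn(reps):
            traj = run_simulation(
                fitness,
                toy_spec1,
                "A",
                n,
                0.0,
                100,
                np.random.default_rng(child),
                initial_population={"A": 5, "C": 5},
            )
            assert traj[-1] in (1.0, 2.0)  # absorbed by generation 100
            fixed += traj[-1] == 2.0
        p_hat = fixed / reps
        sigma = np.sqrt(expected * (1 - expected) / reps)
        assert abs(p_hat - expected) < 4.5 * sigma

    def test_fitter_type_fixes_more_often_than_its_frequency(self, toy_spec1):
        # selection sanity on the same chain: p_fix(A) > initial frequency
        expected = wf_fixation_probability(10, 2.0, 1.0, start_a=5)
        assert expected > 0.5

    def test_neutral_martingale(self, toy_spec1):
        """mu=0, equal fitness: mean final frequency equals the initial one."""
        reps, n = 2000, 10
        fitness = pd.Series({"A": 1.0, "C": 1.0, "G": 0.0, "U": 0.0}).reindex(
            build_library(toy_spec1)
        )
        master = np.random.SeedSequence(99)
        freqs = []
        for child in master.spawn(reps):
            _, pop = run_simulation(
                fitness,
                toy_spec1,
                "A",
                n,
                0.0,
                80,
                np.random.default_rng(child),
                initial_population={"A": 5, "C": 5},
                return_population=True,
            )
            freqs.append(pop.get("A", 0) / n)
        sigma = 0.5 / np.sqrt(reps)
        assert abs(np.mean(freqs) - 0.5) < 4.5 * sigma


class TestChooseStart:
    def _landscape_peaked_at_wild_type(self, spec):
        wt = spec.wild_type_alleles
        d = distances_to(wt, spec.n_positions)
        fitness = pd.Series(0.5 ** d, index=build_library(spec))
        return FitnessLandscape.from_slices(
            {(1.0, 1): fitness, (48.0, 1): fitness}
        )

    def test_distance_constraint_and_lexicographic_tie_break(self, default_spec):
        landscape = self._landscape_peaked_at_wild_type(default_spec)
        choice = choose_start(landscape, default_spec)
        assert choice.min_distance_to_peaks == 7
        assert not choice.relaxed
        # all distance-7 genotypes tie in fitness; smallest lexicographically
        # substitutes the smallest non-wild-type allele at every position
        assert choice.genotype == "ACCCAAA"
        assert all(
            distances_to(peak, 7)[
                build_library(default_spec).index(choice.genotype)
            ]
            == 7
            for peak in choice.peaks.values()
        )

    def test_relaxes_when_distance_unreachable(self, toy_spec2):
        # peak at "AA": every genotype is within distance 2, so asking for
        # more than 2 must relax to the max achievable distance
        library = build_library(toy_spec2)
        d = distances_to("AA", 2)
        fitness = pd.Series(0.5 ** d, index=library)
        landscape = FitnessLandscape.from_slices({(1.0, 1): fitness})
        choice = choose_start(landscape, toy_spec2, target_distance=5)
        assert choice.relaxed
        assert choice.min_distance_to_peaks == 2


class TestBatchSimulate:
    def test_same_master_seed_is_identical(self, toy_spec2):
        fitness = flat_fitness(toy_spec2)
        cfg = SimConfig(
            population_size=30,
            mutation_rate=0.02,
            generations=20,
            replicates=4,
            rng_seed=5,
        )
        t1, m1 = batch_simulate(fitness, toy_spec2, cfg, "AA")
        t2, m2 = batch_simulate(fitness, toy_spec2, cfg, "AA")
        np.testing.assert_array_equal(t1, t2)
        np.testing.assert_array_equal(m1, m2)
        assert t1.shape == (4, 21)

    def test_single_replicate_mean_is_the_trajectory(self, toy_spec2):
        fitness = flat_fitness(toy_spec2)
        cfg = SimConfig(
            population_size=20,
            mutation_rate=0.0,
            generations=15,
            replicates=1,
            rng_seed=3,
        )
        trajs, mean = batch_simulate(fitness, toy_spec2, cfg, "AA")
        np.testing.assert_array_equal(trajs[0], mean)


class TestLogisticFit:
    def test_exact_logistic_recovered(self):
        x = np.arange(0, 2001)
        y = logistic_curve(x, 2.0, 0.1, 50.0)
        fit = fit_logistic(y)
        assert fit.converged
        assert abs(fit.L - 2.0) / 2.0 < 1e-4
        assert abs(fit.k - 0.1) / 0.1 < 1e-4
        assert abs(fit.x0 - 50.0) / 50.0 < 1e-4

    def test_constant_trajectory_flagged_degenerate(self):
        fit = fit_logistic(np.full(100, 0.3))
        assert not fit.converged
        assert fit.reason == "degenerate_flat"


class TestG50:
    def test_flat_landscape_g50_is_one(self, toy_spec2):
        fitness = flat_fitness(toy_spec2)
        cfg = SimConfig(
            population_size=30,
            mutation_rate=0.01,
            generations=60,
            replicates=3,
            rng_seed=1,
        )
        trajs, _ = batch_simulate(fitness, toy_spec2, cfg, "AA")
        assert g50(trajs) == pytest.approx(1.0)

    def test_no_mutation_low_start_keeps_start_fitness(self, toy_spec2, rng):
        fitness = flat_fitness(toy_spec2)
        fitness.loc["AA"] = 0.2
        traj = run_simulation(fitness, toy_spec2, "AA", 40, 0.0, 60, rng)
        assert g50(traj) == pytest.approx(0.2)

    def test_short_trajectories_rejected(self):
        with pytest.raises(ValueError):
            g50(np.ones((3, 40)))
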