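"""Wright-Fisher simulation of populations evolving on an empirical landscape.

Discrete, non-overlapping generations at constant population size N: each
generation, N offspring are drawn with replacement with probability
proportional to parental fitness (fitness-proportional reproduction), and
each offspring independently mutates with probability mu to one of its
``3L`` single-substitution neighbors, chosen uniformly.  The per-generation
population mean fitness is the recorded trajectory; adaptation is summarized
by a logistic fit ``f(x) = L / (1 + exp(-k (x - x0)))`` of the
cross-replicate mean trajectory, and by the mean fitness at generation 50
(the "G50" statistic).

Trajectory arrays have length ``generations + 1``: index 0 is the initial
monomorphic population and index g is the state after g generations, so
"generation 50" is index 50.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .fitness import FitnessLandscape
from .genotypes import (
    LibrarySpec,
    build_library,
    distances_to,
    genotype_to_index,
    index_to_genotype,
    neighbor_index_table,
)

__all__ = [
    "SimConfig",
    "ExtinctionError",
    "StartChoice",
    "choose_start",
    "run_simulation",
    "batch_simulate",
    "LogisticFit",
    "fit_logistic",
    "g50",
]


class ExtinctionError(RuntimeError):
    """Total population fitness reached 0; no individual can reproduce."""

    def __init__(self, generation: int):
        self.generation = generation
        super().__init__(f"population fitness is 0 at generation {generation}")


@dataclass(frozen=True)
class SimConfig:
    population_size: int = 1000
    mutation_rate: float = 0.01
    generations: int = 2000
    replicates: int = 100
    start_genotype: str = "auto"
    rng_seed: int = 0

    def __post_init__(self):
        if self.population_size < 1:
            raise ValueError("population_size must be >= 1")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass(frozen=True)
class StartChoice:
    genotype: str
    min_distance_to_peaks: int
    mean_fitness: float
    peaks: dict
    relaxed: bool = False


def _fitness_vector(fitness: pd.Series, spec: LibrarySpec) -> np.ndarray:
    values = fitness.reindex(build_library(spec)).to_numpy(dtype=float)
    return np.nan_to_num(values, nan=0.0)  # missing genotypes cannot reproduce


def choose_start(
    landscape: FitnessLandscape,
    spec: LibrarySpec,
    target_distance: int | None = None,
) -> StartChoice:
    """Deterministic low-fitness start far from every per-mg fitness peak.

    Finds the per-mg top-fitness genotype (replicate-mean), then selects the
    genotype at Hamming distance ``target_distance`` (default: the number of
    variable positions) from every one of those peaks that has nonzero
    fitness in every condition and the lowest across-condition mean fitness;
    ties break lexicographically.  If no genotype satisfies the distance
    constraint, the largest achievable min-distance is used and the choice is
    flagged ``relaxed``.  Requiring nonzero fitness everywhere keeps the
    starting population viable under fitness-proportional reproduction.
    """
    L = spec.n_positions
    target = L if target_distance is None else target_distance
    library = build_library(spec)
    slices = {mg: _fitness_vector(landscape.slice(mg), spec) for mg in landscape.mg_levels}
    peaks = {mg: library[int(np.argmax(v))] for mg, v in slices.items()}
    min_dist = np.full(4**L, L + 1, dtype=np.int64)
    for mg, peak in peaks.items():
        d = distances_to(peak, L)
        min_dist = np.minimum(min_dist, d)
    mean_fit = np.mean(np.stack(list(slices.values())), axis=0)
    alive = np.all(np.stack(list(slices.values())) > 0, axis=0)

    relaxed = False
    candidates = (min_dist == target) & alive
    if not candidates.any():
        relaxed = True
        achievable = int(min_dist[alive].max()) if alive.any() else 0
        if achievable == 0:
            raise ValueError("no viable start genotype exists")
        candidates = (min_dist == achievable) & alive
        target = achievable
    idx = np.nonzero(candidates)[0]
    best = idx[np.lexsort((idx, mean_fit[idx]))][0]  # min fitness, lex tie-break
    genotype = library[int(best)]
    return StartChoice(
        genotype=genotype,
        min_distance_to_peaks=int(min_dist[best]),
        mean_fitness=float(mean_fit[best]),
        peaks=peaks,
        relaxed=relaxed,
    )


def run_simulation(
    fitness: pd.Series,
    spec: LibrarySpec,
    start_genotype: str,
    population_size: int,
    mutation_rate: float,
    generations: int,
    rng,
    initial_population: dict[str, int] | None = None,
    return_population: bool = False,
):
    """One Wright-Fisher run on a landscape slice -> mean-fitness trajectory.

    ``fitness`` is the genotype -> fitness map of one condition (missing
    values count as fitness 0).  ``initial_population`` (genotype -> count,
    summing to N) overrides the default monomorphic start; useful for
    fixation experiments.  Fully reproducible from ``rng``.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    f = _fitness_vector(fitness, spec)
    L = spec.n_positions
    nbr = neighbor_index_table(L)
    n_nbr = nbr.shape[1]
    uniform = np.full(n_nbr, 1.0 / n_nbr)
    N = int(population_size)

    counts = np.zeros(4**L, dtype=np.int64)
    if initial_population is None:
        counts[genotype_to_index(start_genotype)] = N
    else:
        for g, c in initial_population.items():
            counts[genotype_to_index(g)] += int(c)
        if counts.sum() != N:
            raise ValueError("initial_population must sum to population_size")

    traj = np.empty(generations + 1)
    traj[0] = float(counts @ f) / N
    for gen in range(1, generations + 1):
        weights = counts * f
        total = weights.sum()
        if total <= 0:
            raise ExtinctionError(gen)
        offspring = rng.multinomial(N, weights / total)
        if mutation_rate > 0:
            for g in np.nonzero(offspring)[0]:
                m = rng.binomial(offspring[g], mutation_rate)
                if m:
                    offspring[g] -= m
                    offspring[nbr[g]] += rng.multinomial(m, uniform)
        counts = offspring
        if counts.sum() != N:  # population size is invariant by construction
            raise RuntimeError("population size drifted; internal error")
        traj[gen] = float(counts @ f) / N
    if return_population:
        pop = {
            index_to_genotype(int(i), L): int(counts[i])
            for i in np.nonzero(counts)[0]
        }
        return traj, pop
    return traj


def batch_simulate(
    fitness: pd.Series,
    spec: LibrarySpec,
    config: SimConfig,
    start_genotype: str | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Independent seeded replicates -> (trajectories, cross-replicate mean).

    One master seed deterministically spawns per-replicate child streams;
    ``trajectories`` has shape (replicates, generations + 1).
    """
    start = start_genotype or config.start_genotype
    if start == "auto":
        raise ValueError("resolve start_genotype with choose_start first")
    children = np.random.SeedSequence(config.rng_seed).spawn(config.replicates)
    trajs = np.stack(
        [
            run_simulation(
                fitness,
                spec,
                start,
                config.population_size,
                config.mutation_rate,
                config.generations,
                np.random.default_rng(child),
            )
            for child in children
        ]
    )
    return trajs, trajs.mean(axis=0)


@dataclass(frozen=True)
class LogisticFit:
    """Logistic fit of a mean trajectory: asymptote L, rate k, midpoint x0."""

    L: float
    k: float
    x0: float
    residual: float
    converged: bool
    reason: str | None = None


def logistic_curve(x, L, k, x0):
    x = np.asarray(x, dtype=float)
    return L / (1.0 + np.exp(-k * (x - x0)))


def fit_logistic(mean_trajectory, generations=None) -> LogisticFit:
    """Nonlinear least squares of the logistic growth law on a trajectory."""
    y = np.asarray(mean_trajectory, dtype=float)
    x = np.arange(y.size) if generations is None else np.asarray(generations, float)
    if y.size < 5:
        raise ValueError("need at least 5 points")
    span = y.max() - y.min()
    if span <= 1e-9 * max(abs(y.max()), 1e-12):
        return LogisticFit(
            float(y.mean()), np.nan, np.nan, float(np.std(y)), False, "degenerate_flat"
        )
    L0 = float(y.max())
    half = 0.5 * L0
    above = np.nonzero(y >= half)[0]
    x0_init = float(x[above[0]]) if above.size else float(x[-1])
    bounds = ([1e-9, 1e-6, 0.0], [np.inf, 10.0, 100.0 * float(x[-1] + 1)])
    best = None
    for k0 in (0.01, 0.05, 0.1, 0.5):
        start = np.clip([L0, k0, x0_init], bounds[0], bounds[1])
        try:
            sol = least_squares(
                lambda th: logistic_curve(x, *th) - y,
                start,
                bounds=bounds,
                xtol=1e-12,
                ftol=1e-12,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return LogisticFit(np.nan, np.nan, np.nan, np.nan, False, "solver_failure")
    Lv, kv, x0v = best.x
    return LogisticFit(
        float(Lv),
        float(kv),
        float(x0v),
        float(np.sqrt(2 * best.cost / y.size)),
        bool(best.success),
        None,
    )


def g50(trajectories: np.ndarray, generation: int = 50) -> float:
    """Cross-replicate mean of population mean fitness at one generation."""
    trajs = np.atleast_2d(np.asarray(trajectories, dtype=float))
    if trajs.shape[1] <= generation:
        raise ValueError(
            f"trajectories too short ({trajs.shape[1] - 1} generations) "
            f"for generation {generation}"
        )
    return float(trajs[:, generation].mean())
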