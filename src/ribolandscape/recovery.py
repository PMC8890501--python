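"""Designed parameter-recovery and gradient-reproduction experiments.

These are the package's built-in benchmark experiments: self-contained
synthetic studies that exercise the full measurement chain (truth ->
selection -> multinomial sequencing -> fitness -> curve fits / topography /
simulation) and compare what comes out against what went in.  They back the
validation suite and the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .dose_response import fit_hill
from .evolution import SimConfig, batch_simulate, choose_start, fit_logistic, g50
from .fitness import FitnessLandscape, compute_fitness
from .genotypes import LibrarySpec
from .synthetic import GeneratorParams, simulate_counts, simulate_experiment
from .topography import ruggedness, ruggedness_trend

__all__ = [
    "hill_recovery_experiment",
    "fit_recovered_midpoints",
    "measured_landscape",
    "landscape_gradient_experiment",
]

MG_LEVELS = np.array([1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 16.0, 48.0])


def hill_recovery_experiment(
    n_genotypes: int = 1000,
    depth: int = 100_000,
    replicates: int = 3,
    seed: int = 0,
    mg_levels=MG_LEVELS,
) -> dict:
    """Simulate a titration of known Hill-curve variants and measure them.

    The pool holds ``n_genotypes`` variants with parameters drawn from the
    generator's regime (wmax log-uniform in [0.3, 2.5], midpoint log-uniform
    in [2, 14] mM, slope 3) plus a saturated spike-in reference (midpoint
    far below the titration range) at 10% of the pool, so each variant's
    normalized fitness profile is exactly its own Hill curve.  Sequencing is
    multinomial at ``depth`` per condition-replicate; replicate profiles are
    combined by inverse-variance weighting using count-based standard
    errors.

    Returns ``{"truth": DataFrame, "profiles": DataFrame, "sigmas":
    DataFrame}`` with one row per variant and one column per mg level.
    """
    rng = np.random.default_rng(seed)
    mg_levels = np.asarray(mg_levels, dtype=float)
    wmax = np.exp(rng.uniform(np.log(0.3), np.log(2.5), n_genotypes))
    k = np.exp(rng.uniform(np.log(2.0), np.log(14.0), n_genotypes))
    names = [f"v{i}" for i in range(n_genotypes)] + ["ref"]
    truth = pd.DataFrame(
        {
            "wmax_true": np.r_[wmax, 1.0],
            "k_true": np.r_[k, 0.01],
            "h_true": 3.0,
            "dead": False,
        },
        index=pd.Index(names, name="genotype"),
    )
    pool = pd.Series(
        np.r_[np.full(n_genotypes, 0.9 / n_genotypes), 0.1], index=truth.index
    )
    profiles, sigmas = [], []
    for mg in mg_levels:
        values, errors = [], []
        for _ in range(replicates):
            pre_c, post_c = simulate_counts(truth, mg, depth, pool, rng)
            w = compute_fitness(
                pre_c / pre_c.sum(), post_c / post_c.sum(), "ref"
            )
            # counting-noise standard error of a ratio of proportions;
            # +1 / floor terms keep zero-count points finite
            se = np.maximum(w, 1e-3) * np.sqrt(
                1.0 / pre_c.clip(lower=1) + 1.0 / (post_c + 1)
            ) + (post_c == 0) * 0.01
            values.append(w)
            errors.append(se)
        w_mat = pd.concat(values, axis=1)
        s_mat = pd.concat(errors, axis=1)
        inv_var = 1.0 / s_mat**2
        profiles.append((w_mat * inv_var).sum(axis=1) / inv_var.sum(axis=1))
        sigmas.append(np.sqrt(1.0 / inv_var.sum(axis=1)))
    prof = pd.concat(profiles, axis=1)
    prof.columns = mg_levels
    sig = pd.concat(sigmas, axis=1)
    sig.columns = mg_levels
    variants = names[:n_genotypes]
    return {
        "truth": truth.loc[variants],
        "profiles": prof.loc[variants],
        "sigmas": sig.loc[variants],
    }


def fit_recovered_midpoints(experiment: dict, weighted: bool = True) -> pd.DataFrame:
    """Fit every measured profile; returns per-variant k_true, k_hat, rel_err."""
    mg = experiment["profiles"].columns.to_numpy(dtype=float)
    rows = {}
    for genotype, profile in experiment["profiles"].iterrows():
        sigma = experiment["sigmas"].loc[genotype].to_numpy() if weighted else None
        fit = fit_hill(mg, profile.to_numpy(), sigma=sigma, genotype=genotype)
        k_true = experiment["truth"].loc[genotype, "k_true"]
        rows[genotype] = {
            "k_true": k_true,
            "k_hat": fit.k,
            "wmax_hat": fit.wmax,
            "h_hat": fit.h,
            "converged": fit.converged,
            "rel_err_k": abs(fit.k - k_true) / k_true,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def measured_landscape(
    spec: LibrarySpec, params: GeneratorParams, seed: int
) -> tuple[FitnessLandscape, pd.DataFrame]:
    """Run the synthetic experiment and return (measured landscape, truth)."""
    experiment = simulate_experiment(spec, params, seed=seed)
    wt = spec.wild_type_alleles
    slices = {}
    for (mg, rep, phase), counts in experiment["counts"].items():
        if phase != "pre":
            continue
        post = experiment["counts"][(mg, rep, "post")]
        slices[(mg, rep)] = compute_fitness(
            counts / counts.sum(), post / post.sum(), wt
        )
    return FitnessLandscape.from_slices(slices), experiment["truth"]


@dataclass(frozen=True)
class GradientResult:
    """Per-mg topography and adaptation summaries plus their mg trends."""

    table: pd.DataFrame  # mg_mM, ruggedness, x0, g50, L, k
    ruggedness_rho: float
    x0_rho: float
    g50_rho: float


def landscape_gradient_experiment(
    seed: int,
    sim_generations: int = 300,
    sim_replicates: int = 10,
    population_size: int = 1000,
    mutation_rate: float = 0.01,
    spec: LibrarySpec | None = None,
    params: GeneratorParams | None = None,
) -> GradientResult:
    """Magnesium-gradient study on one synthetic experiment.

    Measures, for each of the magnesium levels (the stabilization gradient),
    the ruggedness of the measured landscape and the adaptation summaries
    (logistic midpoint x0, G50) of Wright-Fisher populations started from a
    deterministically chosen low-fitness genotype far from every peak; then
    the Spearman trends of each against magnesium.
    """
    spec = spec or LibrarySpec()
    params = params or GeneratorParams()
    landscape, _ = measured_landscape(spec, params, seed)
    start = choose_start(landscape, spec)
    rows = []
    for i, mg in enumerate(landscape.mg_levels):
        fitness = landscape.slice(mg)
        rug = ruggedness(fitness, spec)
        cfg = SimConfig(
            population_size=population_size,
            mutation_rate=mutation_rate,
            generations=sim_generations,
            replicates=sim_replicates,
            start_genotype=start.genotype,
            rng_seed=int(
                np.random.SeedSequence((seed, i)).generate_state(1)[0]
            )
            % (2**31),
        )
        trajs, mean = batch_simulate(fitness, spec, cfg, start.genotype)
        log_fit = fit_logistic(mean)
        rows.append(
            {
                "mg_mM": mg,
                "ruggedness": rug.ruggedness,
                "f_sign": rug.f_sign,
                "f_reciprocal_sign": rug.f_reciprocal_sign,
                "x0": log_fit.x0,
                "L": log_fit.L,
                "k": log_fit.k,
                "g50": g50(trajs),
            }
        )
    table = pd.DataFrame(rows)
    return GradientResult(
        table=table,
        ruggedness_rho=ruggedness_trend(table["mg_mM"], table["ruggedness"]).rho,
        x0_rho=ruggedness_trend(table["mg_mM"], table["x0"]).rho,
        g50_rho=ruggedness_trend(table["mg_mM"], table["g50"]).rho,
    )
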