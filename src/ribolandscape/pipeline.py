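"""End-to-end pipeline orchestration: config, stages, output manifest.

A single YAML config describes the library, the synthetic generator (when no
real reads are provided), and the analysis stages to run.  Every stage writes
flat TSV/JSON outputs into the run directory and the pipeline finishes by
writing ``manifest.json`` with a content hash for every output file, the
master seed, and per-stage timings — reruns with the same config and seed
produce identical hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import counting, dose_response, evolution, synthetic, topography
from .counting import CountTable, compile_matcher, count_reads
from .fitness import FitnessLandscape, compute_fitness
from .genotypes import LibrarySpec, LibraryValidationError
from .synthetic import GeneratorParams

__all__ = ["RunConfig", "validate_config", "run_pipeline", "ALL_STAGES"]

ALL_STAGES = ("simulate", "count", "fitness", "topography", "doseresponse", "evolve")


@dataclass
class RunConfig:
    library: LibrarySpec = field(default_factory=LibrarySpec)
    generator: GeneratorParams = field(default_factory=GeneratorParams)
    simulation: evolution.SimConfig = field(default_factory=evolution.SimConfig)
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    read_depth: int | None = None  # overrides generator.read_depth
    emit_fastq: bool = True
    contaminant_fraction: float = 0.0
    allow_reverse_complement: bool = False
    classification_eps: float = 0.0
    evolve_mg: tuple[float, ...] | None = None  # default: all mg levels

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        kwargs = dict(data)
        if "library" in kwargs:
            kwargs["library"] = LibrarySpec(**kwargs["library"])
        if "generator" in kwargs:
            kwargs["generator"] = GeneratorParams(**kwargs["generator"])
        if "simulation" in kwargs:
            kwargs["simulation"] = evolution.SimConfig(**kwargs["simulation"])
        if "stages" in kwargs:
            kwargs["stages"] = tuple(kwargs["stages"])
        if kwargs.get("evolve_mg") is not None:
            kwargs["evolve_mg"] = tuple(kwargs["evolve_mg"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)


def validate_config(data: dict) -> list[str]:
    """Validate a raw config mapping; returns all violations found (empty = valid)."""
    violations: list[str] = []
    for section, builder in (
        ("library", LibrarySpec),
        ("generator", GeneratorParams),
        ("simulation", evolution.SimConfig),
    ):
        try:
            builder(**data.get(section, {}))
        except (LibraryValidationError, ValueError, TypeError) as exc:
            violations.append(f"{section}: {exc}")
    for stage in data.get("stages", ALL_STAGES):
        if stage not in ALL_STAGES:
            violations.append(f"stages: unknown stage {stage!r}")
    if "seed" in data and not isinstance(data["seed"], int):
        violations.append("seed: must be an integer")
    cf = data.get("contaminant_fraction", 0.0)
    if not 0.0 <= float(cf) <= 1.0:
        violations.append("contaminant_fraction: must be in [0, 1]")
    return violations


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _condition_tag(mg: float, rep: int, phase: str) -> str:
    mg_tag = f"{mg:g}".replace(".", "p")
    return f"mg{mg_tag}_rep{rep}_{phase}"


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest.

    Stage outputs (all under ``outdir``): truth/pool tables and FASTQ or
    count TSVs (simulate), count tables (count), long + aggregated fitness
    TSVs (fitness), ruggedness/roughness summaries (topography), Hill and
    decay fit tables (doseresponse), trajectories and logistic/G50 summaries
    (evolve).  A stage failure aborts with the stage name and cause.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = config.library
    depth = config.read_depth or config.generator.read_depth
    stages = tuple(config.stages)
    manifest: dict = {"seed": config.seed, "stages": {}, "files": {}}
    state: dict = {}

    def record(path: Path):
        manifest["files"][str(path.relative_to(outdir))] = _sha256(path)

    def run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3)}

    # ---- simulate ----------------------------------------------------------
    def stage_simulate():
        experiment = synthetic.simulate_experiment(
            spec, config.generator, seed=config.seed, depth=depth
        )
        state["truth"] = experiment["truth"]
        truth_path = outdir / "truth.tsv"
        experiment["truth"].to_csv(truth_path, sep="\t")
        record(truth_path)
        pool_path = outdir / "pool.tsv"
        experiment["pool"].rename("proportion").to_csv(pool_path, sep="\t")
        record(pool_path)
        fastq_rng = np.random.default_rng(
            np.random.SeedSequence((config.seed, 1))
        )
        tables = {}
        for (mg, rep, phase), counts in experiment["counts"].items():
            condition = {"mg_mM": mg, "replicate": rep, "phase": phase}
            tag = _condition_tag(mg, rep, phase)
            if config.emit_fastq:
                fq = outdir / "reads" / f"{tag}.fastq"
                synthetic.write_fastq(
                    counts,
                    spec,
                    fq,
                    contaminant_fraction=config.contaminant_fraction,
                    rng=fastq_rng,
                )
                record(fq)
            else:
                table = CountTable.from_series(counts, condition=condition)
                path = outdir / "counts" / f"{tag}.tsv"
                table.to_tsv(path)
                record(path)
                record(path.with_suffix(".tsv.json"))
                tables[(mg, rep, phase)] = table
        if not config.emit_fastq:
            state["counts"] = tables

    # ---- count -------------------------------------------------------------
    def stage_count():
        if "counts" in state:  # simulate already produced count tables
            return
        matcher = compile_matcher(spec, config.allow_reverse_complement)
        tables = {}
        for mg in spec.mg_levels:
            for rep in range(1, spec.replicates + 1):
                for phase in ("pre", "post"):
                    tag = _condition_tag(mg, rep, phase)
                    fq = outdir / "reads" / f"{tag}.fastq"
                    condition = {"mg_mM": mg, "replicate": rep, "phase": phase}
                    table = count_reads(fq, matcher, condition=condition)
                    path = outdir / "counts" / f"{tag}.tsv"
                    table.to_tsv(path)
                    record(path)
                    record(path.with_suffix(".tsv.json"))
                    tables[(mg, rep, phase)] = table
        state["counts"] = tables

    # ---- fitness -----------------------------------------------------------
    def stage_fitness():
        tables = state.get("counts")
        if tables is None:
            tables = {}
            for mg in spec.mg_levels:
                for rep in range(1, spec.replicates + 1):
                    for phase in ("pre", "post"):
                        tag = _condition_tag(mg, rep, phase)
                        tables[(mg, rep, phase)] = CountTable.from_tsv(
                            outdir / "counts" / f"{tag}.tsv"
                        )
        wt = spec.wild_type_alleles
        slices = {}
        for mg in spec.mg_levels:
            for rep in range(1, spec.replicates + 1):
                pre = counting.proportions(tables[(mg, rep, "pre")])
                post = counting.proportions(tables[(mg, rep, "post")])
                slices[(mg, rep)] = compute_fitness(pre, post, wt)
        landscape = FitnessLandscape.from_slices(slices)
        state["landscape"] = landscape
        long_path = outdir / "fitness.tsv"
        landscape.to_tsv(long_path)
        record(long_path)
        agg = []
        for mg in spec.mg_levels:
            df = landscape.aggregate(mg).reset_index()
            df.insert(1, "mg_mM", mg)
            agg.append(df)
        agg_path = outdir / "fitness_aggregated.tsv"
        pd.concat(agg, ignore_index=True).to_csv(agg_path, sep="\t", index=False)
        record(agg_path)

    def _landscape() -> FitnessLandscape:
        if "landscape" not in state:
            state["landscape"] = FitnessLandscape.from_tsv(outdir / "fitness.tsv")
        return state["landscape"]

    # ---- topography --------------------------------------------------------
    def stage_topography():
        landscape = _landscape()
        rug_rows, rs_rows = [], []
        for mg in landscape.mg_levels:
            for rep in [*landscape.replicates, "mean"]:
                fit = landscape.slice(mg, None if rep == "mean" else rep)
                res = topography.ruggedness(fit, spec, eps=config.classification_eps)
                rug_rows.append(
                    {
                        "mg_mM": mg,
                        "replicate": rep,
                        "f_none": res.f_none,
                        "f_magnitude": res.f_magnitude,
                        "f_sign": res.f_sign,
                        "f_reciprocal_sign": res.f_reciprocal_sign,
                        "ruggedness": res.ruggedness,
                        "n_squares": res.n_squares,
                        "n_skipped": res.n_skipped,
                    }
                )
            rs = topography.roughness_slope(landscape.slice(mg), spec)
            rs_rows.append(
                {
                    "mg_mM": mg,
                    "roughness": rs.roughness,
                    "slope": rs.slope,
                    "ratio": rs.ratio,
                }
            )
        rug_df = pd.DataFrame(rug_rows)
        rug_path = outdir / "ruggedness.tsv"
        rug_df.to_csv(rug_path, sep="\t", index=False)
        record(rug_path)
        rs_path = outdir / "roughness_slope.tsv"
        pd.DataFrame(rs_rows).to_csv(rs_path, sep="\t", index=False)
        record(rs_path)
        per_rep = rug_df[rug_df["replicate"] != "mean"]
        trend = topography.ruggedness_trend(
            per_rep["mg_mM"].to_numpy(float), per_rep["ruggedness"].to_numpy(float)
        )
        trend_path = outdir / "ruggedness_trend.json"
        trend_path.write_text(
            json.dumps({"rho": trend.rho, "pvalue": trend.pvalue, "n": trend.n})
        )
        record(trend_path)

    # ---- doseresponse ------------------------------------------------------
    def stage_doseresponse():
        landscape = _landscape()
        fits = dose_response.fit_hill_landscape(landscape, spec)
        filtered, tally = dose_response.filter_hill_fits(fits)
        hill_path = outdir / "hill_fits.tsv"
        filtered.to_csv(hill_path, sep="\t")
        record(hill_path)
        tally_path = outdir / "hill_filter_tally.json"
        tally_path.write_text(json.dumps(tally, indent=2))
        record(tally_path)
        mids = dose_response.midpoints_by_distance(filtered[filtered["kept"]])
        mids_path = outdir / "midpoints_by_distance.tsv"
        mids.to_csv(mids_path, sep="\t")
        record(mids_path)
        decay = dose_response.fit_decay_landscape(landscape, spec)
        decay_path = outdir / "decay_fits.tsv"
        decay.to_csv(decay_path, sep="\t")
        record(decay_path)

    # ---- evolve ------------------------------------------------------------
    def stage_evolve():
        landscape = _landscape()
        sim = config.simulation
        if sim.start_genotype == "auto":
            start = evolution.choose_start(landscape, spec)
            start_genotype = start.genotype
            audit = dataclasses.asdict(start)
        else:
            start_genotype = sim.start_genotype
            audit = {"genotype": start_genotype, "source": "config"}
        (outdir / "start_genotype.json").write_text(json.dumps(audit, indent=2))
        record(outdir / "start_genotype.json")
        mg_levels = config.evolve_mg or landscape.mg_levels
        summary_rows, traj_rows = [], []
        for i, mg in enumerate(mg_levels):
            cfg = dataclasses.replace(
                sim,
                start_genotype=start_genotype,
                rng_seed=int(
                    np.random.SeedSequence((sim.rng_seed, i)).generate_state(1)[0]
                )
                % (2**31),
            )
            trajs, mean = evolution.batch_simulate(
                landscape.slice(mg), spec, cfg, start_genotype
            )
            log_fit = evolution.fit_logistic(mean)
            summary_rows.append(
                {
                    "mg_mM": mg,
                    "L": log_fit.L,
                    "k": log_fit.k,
                    "x0": log_fit.x0,
                    "converged": log_fit.converged,
                    "g50": evolution.g50(trajs),
                }
            )
            for rep in range(trajs.shape[0]):
                for gen in range(trajs.shape[1]):
                    traj_rows.append(
                        {
                            "mg_mM": mg,
                            "replicate": rep + 1,
                            "generation": gen,
                            "mean_fitness": trajs[rep, gen],
                        }
                    )
        traj_path = outdir / "trajectories.tsv"
        pd.DataFrame(traj_rows).to_csv(traj_path, sep="\t", index=False)
        record(traj_path)
        summary_path = outdir / "evolution_summary.tsv"
        pd.DataFrame(summary_rows).to_csv(summary_path, sep="\t", index=False)
        record(summary_path)

    stage_fns = {
        "simulate": stage_simulate,
        "count": stage_count,
        "fitness": stage_fitness,
        "topography": stage_topography,
        "doseresponse": stage_doseresponse,
        "evolve": stage_evolve,
    }
    for name in ALL_STAGES:
        if name in stages:
            run_stage(name, stage_fns[name])

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
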