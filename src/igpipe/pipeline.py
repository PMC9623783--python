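"""Orchestration of the indirect-prediction study.

The study mirrors the production workflow it emulates:

1. partition genotyped animals (direct GEBV vs indirect targets);
2. benchmark single-step evaluation with every genotype included — its GEBV
   for the target animals are the gold standard;
3. reduced single-step evaluation with only the GEBV-class genotypes;
4. backsolve SNP effects from the reduced GEBV of a random subset;
5. indirect predictions IGP = Z u for the targets, genetic-base adjustment;
6. validation of IGP against the benchmark GEBV (regression, absolute
   differences, genetic trend).

``prepare_study`` runs the two expensive solves once; ``evaluate_subset``
then sweeps backsolving-subset sizes cheaply on top of them.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as igio
from .backsolve import backsolve_snp_effects, select_backsolve_subset
from .genomic import allele_frequencies, center_genotypes
from .igp import adjust_genetic_base, predict_igp
from .pedigree import build_A
from .population import AnimalPartition, GenotypeMatrix, Pedigree, PhenotypeRecords
from .simulate import SimulatedData, SimulationConfig, partition_animals, simulate
from .solver import ModelSpec, SolveOptions, SsgblupResult, VarianceComponents, run_ssgblup
from .validation import ValidationReport, build_report, genetic_trend, regress_gebv_on_igp

logger = logging.getLogger(__name__)

__all__ = [
    "StudyOptions",
    "PreparedStudy",
    "prepare_study",
    "evaluate_subset",
    "subset_size_sweep",
    "StudyResult",
    "run_igp_study",
    "run_pipeline",
]


@dataclass
class StudyOptions:
    """Knobs of the indirect-prediction workflow (solver tolerances,
    blending, APY core, backsolving subset)."""

    blend_beta: float = 0.05
    tol: float = 1e-12
    max_iter: int = 5000
    apy_core_size: int | None = None  # None: direct dense G inverse
    apy_core_seed: int = 0
    backsolve_size: int | None = None  # None: all GEBV-class animals
    backsolve_seed: int = 0
    trend_window: tuple[int, int] | None = None


@dataclass
class PreparedStudy:
    """Everything the subset sweep reuses: partition, both solves, centered
    gene contents on the common frequency scale."""

    pedigree: Pedigree
    genotypes: GenotypeMatrix
    partition: AnimalPartition
    vc: VarianceComponents
    options: StudyOptions
    freqs: object
    Z_gebv: np.ndarray  # rows follow partition.gebv_ids
    Z_targets: np.ndarray  # rows follow partition.igp_ids
    benchmark: SsgblupResult
    reduced: SsgblupResult
    target_sex: np.ndarray
    timings: dict = field(default_factory=dict)


def prepare_study(
    ped: Pedigree,
    geno: GenotypeMatrix,
    phen: PhenotypeRecords,
    vc: VarianceComponents,
    cutoff_year: int,
    options: StudyOptions | None = None,
) -> PreparedStudy:
    """Partition the population and run the benchmark and reduced solves."""
    options = options or StudyOptions()
    t0 = time.perf_counter()
    part = partition_animals(ped, phen, geno, cutoff_year)
    logger.info(
        "partition: %d GEBV (%d%%), %d IGP (%d%%), %d nongenotyped",
        part.gebv_ids.size, part.shares["gebv"], part.igp_ids.size, part.shares["igp"],
        part.nongenotyped_ids.size,
    )
    freqs = allele_frequencies(geno)  # pool frequencies, reused at every stage
    cache = {"A_full": build_A(ped)}
    model = ModelSpec(n_traits=vc.n_traits)

    solve_opts = SolveOptions(blend_beta=options.blend_beta, tol=options.tol, max_iter=options.max_iter)
    if options.apy_core_size is not None:
        rng = np.random.default_rng(options.apy_core_seed)
        solve_opts.apy_core_ids = np.sort(rng.choice(geno.ids, options.apy_core_size, replace=False))
    t1 = time.perf_counter()
    benchmark = run_ssgblup(ped, geno, phen, vc, model, solve_opts, freqs=freqs, cache=cache)
    t2 = time.perf_counter()
    logger.info("benchmark solve: %d iterations, converged=%s", benchmark.iterations, benchmark.converged)

    geno_reduced = geno.subset(part.gebv_ids)
    red_opts = SolveOptions(blend_beta=options.blend_beta, tol=options.tol, max_iter=options.max_iter)
    reduced = run_ssgblup(ped, geno_reduced, phen, vc, model, red_opts, freqs=freqs, cache=cache)
    t3 = time.perf_counter()
    logger.info("reduced solve: %d iterations, converged=%s", reduced.iterations, reduced.converged)

    Z_gebv = center_genotypes(geno, freqs, part.gebv_ids)
    Z_targets = center_genotypes(geno, freqs, part.igp_ids)
    target_sex = ped.sex[ped.positions(part.igp_ids)]
    return PreparedStudy(
        ped, geno, part, vc, options, freqs, Z_gebv, Z_targets, benchmark, reduced, target_sex,
        timings={"partition": t1 - t0, "benchmark_solve": t2 - t1, "reduced_solve": t3 - t2},
    )


def evaluate_subset(prep: PreparedStudy, size: int | None, seed: int, adjust: str | None = "mean_difference"):
    """Backsolve from a random subset, predict the targets, validate.

    Returns ``(metrics_frame, igp_result, effects)`` where the metrics frame
    has one row per trait x sex group with b1, r2 and the correlation of IGP
    with the benchmark GEBV.
    """
    gebv_ids = prep.partition.gebv_ids
    size = gebv_ids.size if size is None else size
    subset = select_backsolve_subset(gebv_ids, size, seed)
    rows = pd.Index(gebv_ids).get_indexer(subset)
    a_hat = prep.reduced.gebv.for_ids(subset)
    effects = backsolve_snp_effects(prep.Z_gebv[rows], a_hat, prep.freqs, prep.options.blend_beta, subset)
    igp = predict_igp(prep.Z_targets, effects, prep.partition.igp_ids)
    bench_targets = prep.benchmark.gebv.for_ids(prep.partition.igp_ids)
    # validation is against the raw predictions: b0 measures the genetic-base
    # gap, which the optional adjustment afterwards removes
    reg = regress_gebv_on_igp(bench_targets, igp.values, prep.target_sex, prep.vc.genetic_sd())
    raw_values = igp.values
    if adjust:
        igp = adjust_genetic_base(igp, prep.benchmark.gebv, mode=adjust)
    corrs = []
    for _, row in reg.iterrows():
        sel = prep.target_sex == row["group"]
        corrs.append(float(np.corrcoef(bench_targets[sel, int(row["trait"])], raw_values[sel, int(row["trait"])])[0, 1]))
    reg = reg.assign(corr_benchmark=corrs, size=size, seed=seed)
    return reg, igp, effects


def subset_size_sweep(prep: PreparedStudy, sizes, seeds) -> pd.DataFrame:
    """Re-run backsolving/prediction/validation over subset sizes and seeds.

    Returns the long table of per-(size, seed, trait, group) metrics; average
    over seeds to get the accuracy/dispersion-vs-size curves.
    """
    frames = []
    for size in sizes:
        for seed in seeds:
            metrics, _, _ = evaluate_subset(prep, size, seed)
            frames.append(metrics)
    return pd.concat(frames, ignore_index=True)


@dataclass
class StudyResult:
    prep: PreparedStudy
    effects: object
    igp: object
    report: ValidationReport
    metrics: pd.DataFrame
    dg: np.ndarray


def run_igp_study(
    ped: Pedigree,
    geno: GenotypeMatrix,
    phen: PhenotypeRecords,
    vc: VarianceComponents,
    cutoff_year: int,
    options: StudyOptions | None = None,
) -> StudyResult:
    """The full workflow at the configured backsolving-subset size."""
    options = options or StudyOptions()
    prep = prepare_study(ped, geno, phen, vc, cutoff_year, options)
    metrics, igp_raw, effects = evaluate_subset(prep, options.backsolve_size, options.backsolve_seed, adjust=None)
    igp = adjust_genetic_base(igp_raw, prep.benchmark.gebv, mode="mean_difference")
    bench_targets = prep.benchmark.gebv.for_ids(prep.partition.igp_ids)
    dg = genetic_trend(
        prep.benchmark.gebv.values, ped.birth_year, vc.genetic_sd(), options.trend_window
    )
    # the report describes the raw predictions; b0 and MEAN expose the
    # genetic-base gap that the delivered (adjusted) predictions remove
    report = build_report(bench_targets, igp_raw.values, prep.target_sex, vc.genetic_sd(), dg)
    return StudyResult(prep, effects, igp, report, metrics, dg)


def run_pipeline(config: dict, outdir) -> dict:
    """File-driven entry point: simulate (or read) inputs, run the study,
    write every table plus a run manifest. Returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if "simulation" in config:
        sim_cfg = SimulationConfig(**config["simulation"])
        data = simulate(sim_cfg)
        ped, geno, phen = data.pedigree, data.genotypes, data.phenotypes
        vc = data.variance_components
        igio.write_pedigree(ped, outdir / "pedigree.csv")
        igio.write_genotypes(geno, outdir / "genotypes.txt")
        igio.write_phenotypes(phen, outdir / "phenotypes.csv")
        igio.write_true_values(data.truth, outdir / "true_values.csv")
        cutoff_year = config.get("cutoff_year", sim_cfg.start_year + sim_cfg.n_generations - 2)
    else:
        ped = igio.read_pedigree(config["pedigree"])
        geno = igio.read_genotypes(config["genotypes"])
        phen = igio.read_phenotypes(config["phenotypes"], ped)
        vc_cfg = config["variance_components"]
        vc = VarianceComponents(
            np.asarray(vc_cfg["additive"]), np.asarray(vc_cfg["residual"]),
            np.asarray(vc_cfg.get("permanent_env")) if vc_cfg.get("permanent_env") is not None else None,
        )
        cutoff_year = config["cutoff_year"]
    options = StudyOptions(**config.get("options", {}))
    result = run_igp_study(ped, geno, phen, vc, cutoff_year, options)

    result.prep.benchmark.gebv.to_frame().to_csv(outdir / "gebv_benchmark.csv", index=False)
    result.prep.reduced.gebv.to_frame().to_csv(outdir / "gebv_reduced.csv", index=False)
    igio.write_snp_effects(result.effects, outdir / "snp_effects.csv")
    pd.DataFrame({"id": result.igp.ids}).assign(
        **{f"t{j}": result.igp.values[:, j] for j in range(result.igp.n_traits)}
    ).to_csv(outdir / "igp.csv", index=False)
    result.report.rounded().to_csv(outdir / "validation_per_trait.csv", index=False)
    if result.report.trend_correlations is not None:
        result.report.trend_correlations.to_csv(outdir / "trend_correlations.csv", index=False)

    manifest = {
        "config": config,
        "partition": {
            "n_gebv": int(result.prep.partition.gebv_ids.size),
            "n_igp": int(result.prep.partition.igp_ids.size),
            "shares": result.prep.partition.shares,
            "cutoff_year": int(cutoff_year),
        },
        "solves": {
            "benchmark": {"iterations": result.prep.benchmark.iterations, "converged": result.prep.benchmark.converged},
            "reduced": {"iterations": result.prep.reduced.iterations, "converged": result.prep.reduced.converged},
        },
        "seeds": {
            "simulation": config.get("simulation", {}).get("seed"),
            "backsolve": options.backsolve_seed,
            "apy_core": options.apy_core_seed,
        },
        "scaling_k": result.prep.benchmark.scaling_k,
        "blend_beta": options.blend_beta,
        "timings_s": {k: round(v, 3) for k, v in result.prep.timings.items()},
        "genetic_trend": result.dg.tolist(),
    }
    igio.write_manifest(manifest, outdir / "manifest.json")
    return manifest
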