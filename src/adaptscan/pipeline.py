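"""End-to-end orchestration of the synthetic study analysis.

``run_pipeline`` is a pure function of (inputs, config): given a global
seed it generates (or loads) every input layer, runs the P_ST scan,
parallelism permutations, cis/trans classification and the F_ST gene
scan, and writes TSV/JSON outputs plus a machine-readable run log.
Identical reruns produce identical outputs because every stochastic stage
draws from its own named child stream of the global seed.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import AnalysisConfig, child_rng
from .datatypes import ExpressionMatrix
from .io import (load_expression_matrix, write_expression_matrix,
                 write_annotation_bed, write_genotype_table)
from .simulate import (StudySimParams, AseSimParams, PopGenSimParams,
                       simulate_study, simulate_ase_experiment, simulate_genotypes)
from . import pst as pst_mod
from . import parallelism as par_mod
from . import cistrans as ct_mod
from . import fst as fst_mod

logger = logging.getLogger("adaptscan")


def _pst_stage_tables(expr: ExpressionMatrix, config: AnalysisConfig,
                      outdir: Path) -> dict[tuple[str, str], pd.DataFrame]:
    """P_ST tables per (pair, stage), written as pst_<pair>_<stage>.tsv."""
    results = {}
    pairs = sorted(expr.meta["pair"].unique())
    for stage in sorted(expr.meta["stage"].unique()):
        stage_expr = expr.subset_samples(expr.meta["stage"] == stage)
        totals = stage_expr.sample_totals()
        filtered = pst_mod.filter_features(stage_expr, config.min_total_counts)
        traits = pst_mod.standardize_by_sample_total(filtered, totals)
        for pair in pairs:
            if config.normalize_median_ratio:
                traits_pair, _ = pst_mod.normalize_warm_by_median_ratio(
                    traits, pair, stage)
            else:
                traits_pair = traits
            table = pst_mod.pst_table(traits_pair, pair, trim=config.trim_extremes)
            table = pst_mod.assign_quantiles_and_outliers(
                table, config.pst_outlier_quantile)
            table.to_csv(outdir / f"pst_{pair}_{stage}.tsv", sep="\t")
            results[(pair, stage)] = table
    return results


def _parallelism_report(pst_tables, truth: pd.DataFrame,
                        config: AnalysisConfig, outdir: Path) -> dict:
    B = config.permutation_reps
    report: dict = {"x_enrichment": {}, "shared_codirectional": {},
                    "codirectional_fraction": {}}
    arms = truth["chrom_arm"]
    stages = sorted({s for (_, s) in pst_tables})
    pairs = sorted({p for (p, _) in pst_tables})
    frac_rows = []
    for stage in stages:
        for pair in pairs:
            tab = pst_tables[(pair, stage)]
            outliers = tab.index[tab["outlier"]]
            rng = child_rng(config.seed, f"xenrich:{pair}:{stage}")
            res = par_mod.x_enrichment_test(outliers, arms.loc[tab.index], B, rng)
            report["x_enrichment"][f"{pair}:{stage}"] = res.summary()
            for type_, ids in (("outlier", outliers),
                               ("nonoutlier", tab.index.difference(outliers))):
                frac_rows.append({"f": float((arms.loc[ids] == "X").mean()),
                                  "stage": stage, "type": type_, "pair": pair})
        for p1, p2 in itertools.combinations(pairs, 2):
            t1, t2 = pst_tables[(p1, stage)], pst_tables[(p2, stage)]
            tested = t1.index.intersection(t2.index)
            o1 = t1.index[t1["outlier"]].intersection(tested)
            o2 = t2.index[t2["outlier"]].intersection(tested)
            d1, d2 = t1["direction"], t2["direction"]
            rng = child_rng(config.seed, f"shared:{p1}:{p2}:{stage}")
            res = par_mod.shared_codirectional_test(o1, o2, d1, d2, tested, B, rng)
            report["shared_codirectional"][f"{p1}-{p2}:{stage}"] = res.summary()
            rng = child_rng(config.seed, f"codirfrac:{p1}:{p2}:{stage}")
            res = par_mod.codirectional_fraction_test(o1, d1, d2, tested, B, rng)
            report["codirectional_fraction"][f"{p1}-{p2}:{stage}"] = res.summary()
    frame = pd.DataFrame(frac_rows)
    if len(stages) >= 2 and frame["pair"].nunique() >= 2:
        report["stage_type_lrt"] = par_mod.stage_type_interaction_lrt(frame)
    with open(outdir / "parallelism_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report


def _cistrans_stage(config: AnalysisConfig, ase_params: AseSimParams,
                    outdir: Path) -> dict:
    report = {}
    for pair in ("MED", "ETH", "SAF"):
        seed_rng = child_rng(config.seed, f"ase-sim:{pair}")
        sim_seed = int(seed_rng.integers(2 ** 31))
        allelic, parental, truth = simulate_ase_experiment(ase_params, sim_seed)
        rng = child_rng(config.seed, f"cistrans:{pair}")
        est = ct_mod.analyze_experiment(allelic, parental,
                                        B=config.bootstrap_reps, rng=rng)
        est.to_csv(outdir / f"cistrans_{pair}.tsv", sep="\t")
        report[pair] = {
            "n_features": len(est),
            "category_counts": est["category"].value_counts().to_dict(),
            "magnitude": ct_mod.magnitude_comparison(est),
        }
    return report


def _fst_stage(config: AnalysisConfig, popgen_params: PopGenSimParams,
               annotation: pd.DataFrame, outdir: Path) -> dict:
    seed_rng = child_rng(config.seed, "popgen-sim")
    gm, _, truth = simulate_genotypes(popgen_params, int(seed_rng.integers(2 ** 31)))
    write_genotype_table(gm, outdir / "genotypes.tsv")
    ann_arm = annotation[annotation["chrom_arm"] == popgen_params.arm]
    scan = fst_mod.fst_gene_scan(gm, ann_arm, "cold", "warm", config=config)
    scan.to_csv(outdir / "fst_genes.tsv", sep="\t")
    called = scan.dropna(subset=["fst_winmax"])
    return {"n_genes_scanned": len(scan),
            "n_win_outliers": int(scan["win_outlier"].sum()),
            "n_snp_outliers": int(scan["snp_outlier"].sum()),
            "mean_winmax": float(called["fst_winmax"].mean()) if len(called) else None}


def run_pipeline(config: AnalysisConfig, outdir,
                 expression_path=None, meta_path=None,
                 study_params: StudySimParams | None = None,
                 ase_params: AseSimParams | None = None,
                 popgen_params: PopGenSimParams | None = None) -> dict:
    """Run every stage and write results under ``outdir``.

    If ``expression_path`` is given the expression layer is loaded from
    disk; otherwise a synthetic study is generated from ``study_params``
    (seeded from the config).  Any stage failure aborts the run with the
    stage name attached.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study_params = study_params or StudySimParams(n_genes=400, stages=("larva", "adult"))
    ase_params = ase_params or AseSimParams(n_genes=100)
    popgen_params = popgen_params or PopGenSimParams(
        n_sites=4000, baseline_fst=0.05, n_outlier_loci=5)

    stage = "simulate"
    log: dict = {"seed": config.seed, "version": __version__,
                 "numpy": np.__version__, "pandas": pd.__version__,
                 "config": {k: (dict(v) if isinstance(v, dict) else v)
                            for k, v in asdict(config).items()}}
    try:
        if expression_path is not None:
            expr = load_expression_matrix(expression_path, meta_path)
            truth = None
            annotation = None
        else:
            sim_seed = int(child_rng(config.seed, "study-sim").integers(2 ** 31))
            expr, truth, annotation = simulate_study(study_params, sim_seed)
            write_expression_matrix(expr, outdir / "expression.tsv",
                                    outdir / "samples.tsv")
            truth.to_csv(outdir / "truth.tsv", sep="\t")
            write_annotation_bed(annotation, outdir / "genes.bed")

        stage = "pst"
        pst_tables = _pst_stage_tables(expr, config, outdir)
        log["pst"] = {f"{p}:{s}": {"n_features": len(t),
                                   "n_outliers": int(t["outlier"].sum())}
                      for (p, s), t in pst_tables.items()}

        if truth is not None:
            stage = "parallelism"
            log["parallelism"] = _parallelism_report(pst_tables, truth, config, outdir)

        stage = "cistrans"
        log["cistrans"] = _cistrans_stage(config, ase_params, outdir)

        if annotation is not None:
            stage = "fst"
            log["fst"] = _fst_stage(config, popgen_params, annotation, outdir)
    except Exception as err:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=float, sort_keys=True)
    return log
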