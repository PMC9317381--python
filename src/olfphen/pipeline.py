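"""End-to-end orchestration: score -> preprocess -> structure -> stats ->
selection -> validation, with per-stage artifacts written as CSV/JSON.

A run is a pure function of its configuration (including the seed): every
random draw derives from the top-level seed, so re-running the same config
reproduces the report bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import preprocess, scoring
from .abc_analysis import abc_analysis
from .cohort import CohortTable, read_cohort_csv
from .group_stats import compare_groups
from .selection import (
    ALGORITHMS,
    EnsembleConfig,
    ensemble_consolidate,
    holdout_split,
    run_feature_selection_ensemble,
    target_contrast,
    tune_classifier,
)
from .simulate import SORTING_VARIABLES, SyntheticConfig, generate_cohort
from .structure import (
    bootstrap_stability,
    compare_clusterers,
    pca_project,
    pca_variable_importance,
    retain_components,
    select_k_by_silhouette,
)
from .validation import validate_feature_sets

SPARSE_SET = ["score_pea", "score_eug"]
SNIFFIN_SUBTESTS = ("olfthresh", "olfdis", "olfident")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (fixed DAG, single seed)."""

    seed: int = 0
    outdir: str | Path | None = None
    synthetic: SyntheticConfig | None = None
    cohort_csv: str | Path | None = None
    sidecar: str | Path | None = None
    k_range: tuple[int, int] = (2, 5)
    n_bootstrap: int = 20
    holdout_fraction: float = 0.2
    ensemble: EnsembleConfig | None = None  # None -> desk-scale fast profile
    validation_runs: int = 100
    yates: bool = True
    diagnosis_target: bool = True  # rerun selection/validation on diagnosis
    min_silhouette: float = 0.1  # below this the run is flagged structureless


def _invert_transform(label: str | None, values: np.ndarray) -> np.ndarray:
    """Undo a recorded ladder transform (for reading TDI off the table)."""
    if label is None:
        return values
    name, _, rest = label.partition("+offset:")
    offset = float(rest) if rest else 0.0
    if name == "log":
        return np.exp(values) - offset
    power = float(name.split(":")[1])
    if power < 0:
        return (-values) ** (1.0 / power) - offset
    return values ** (1.0 / power) - offset


def derive_diagnosis(table: CohortTable) -> np.ndarray:
    """Olfactory diagnosis per subject from the (possibly transformed) table.

    The three Sniffin' subtests are mapped back to their raw scale using the
    recorded transforms, summed to the TDI composite, and thresholded at the
    standard 16.5 / 30.5 cut-offs.
    """
    tdi = np.zeros(table.n_subjects)
    for col in SNIFFIN_SUBTESTS:
        raw = _invert_transform(table.meta[col].transform, table.values[col].to_numpy(float))
        tdi += raw
    return np.array(
        ["anosmia" if t < scoring.ANOSMIA_MAX
         else ("hyposmia" if t <= scoring.NORMOSMIA_MIN else "normosmia")
         for t in tdi]
    )


def _seed_tree(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    names = ["impute", "cluster", "bootstrap", "holdout", "ensemble",
             "validation", "diagnosis"]
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31 - 1)) for n, c in zip(names, children)}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full discovery pipeline and return the consolidated report."""
    seeds = _seed_tree(config.seed)
    report: dict = {"seed": config.seed, "stages": {}}

    # -- input -----------------------------------------------------------
    if config.synthetic is not None:
        table, true_labels = generate_cohort(config.synthetic)
        report["input"] = {"source": "synthetic", "n_subjects": table.n_subjects}
    elif config.cohort_csv is not None:
        table = read_cohort_csv(config.cohort_csv, config.sidecar)
        true_labels = None
        report["input"] = {"source": str(config.cohort_csv), "n_subjects": table.n_subjects}
    else:
        raise ValueError("config needs either a synthetic config or a cohort CSV")
    report["input"]["n_missing_cells"] = table.n_missing

    # -- preprocessing ---------------------------------------------------
    table = preprocess.transform_table(table)
    n_before = table.n_subjects
    table = preprocess.filter_missingness(table, cutoff=0.20)
    if true_labels is not None and table.n_subjects != n_before:
        true_labels = true_labels[np.asarray(table.subject_ids)]
    table = preprocess.impute_chained_rf(table, seed=seeds["impute"])
    report["stages"]["preprocess"] = {
        "transforms": {c: table.meta[c].transform for c in table.values.columns},
        "n_retained_subjects": table.n_subjects,
        "n_retained_variables": len(table.values.columns),
    }
    z_table = preprocess.z_standardize(table)
    olf_cols = z_table.olfaction_columns
    z = z_table.values[olf_cols].to_numpy(float)

    # -- unsupervised structure -------------------------------------------
    model = pca_project(z)
    n_retained = retain_components(model)
    importance = pca_variable_importance(z, model, n_retained)
    abc_imp = abc_analysis(importance.absolute)
    report["stages"]["pca"] = {
        "eigenvalues": model.eigenvalues.tolist(),
        "n_retained": n_retained,
        "explained_pct_retained": float(model.explained_fraction[:n_retained].sum() * 100),
        "importance": dict(zip(olf_cols, importance.signed.tolist())),
        "importance_set_a": [olf_cols[i] for i in sorted(abc_imp.set_a)],
    }

    scores = model.scores[:, :n_retained]
    k_lo, k_hi = config.k_range
    best_k, solutions = select_k_by_silhouette(
        scores, range(k_lo, k_hi + 1), seed=seeds["cluster"]
    )
    solution = solutions[best_k]
    stability = bootstrap_stability(
        scores, solution.labels, n_runs=config.n_bootstrap, seed=seeds["bootstrap"]
    )
    cluster_labels = solution.labels
    report["stages"]["clustering"] = {
        "k": best_k,
        "cluster_sizes": np.bincount(cluster_labels).tolist(),
        "mean_silhouette_per_k": {k: s.mean_silhouette for k, s in solutions.items()},
        "mean_silhouette": solution.mean_silhouette,
        "structure_detected": solution.mean_silhouette >= config.min_silhouette,
        "bootstrap": {
            "n_runs": stability.n_runs,
            "mean_silhouette": stability.mean_silhouette,
            "mean_ari": stability.mean_ari,
        },
        "alternative_clusterers": compare_clusterers(scores, best_k, seed=seeds["cluster"]),
    }
    if true_labels is not None:
        from .structure import adjusted_rand_index

        report["stages"]["clustering"]["ari_vs_truth"] = adjusted_rand_index(
            true_labels, cluster_labels
        )

    # -- group statistics --------------------------------------------------
    diagnosis = derive_diagnosis(table) if set(SNIFFIN_SUBTESTS) <= set(table.values.columns) else None
    comparison = compare_groups(
        table, cluster_labels, diagnosis=diagnosis, yates=config.yates
    )
    report["stages"]["group_stats"] = {
        "n_tests": comparison.n_tests,
        "bonferroni_threshold": comparison.bonferroni_threshold,
        "per_variable": comparison.per_variable.reset_index().to_dict("records"),
        "categorical": comparison.categorical.to_dict("records"),
    }

    # -- feature-selection ensemble ---------------------------------------
    ens_config = config.ensemble or EnsembleConfig.fast(seed=seeds["ensemble"])
    features = table.values  # transformed + imputed, all 18 variables
    xt, xv, yt, yv = holdout_split(
        features, cluster_labels, fraction=config.holdout_fraction, seed=seeds["holdout"]
    )
    matrix = run_feature_selection_ensemble(xt, yt, olf_cols, config=ens_config)
    reduced = ensemble_consolidate(matrix)
    report["stages"]["selection"] = {
        "sum_score": matrix.sum_score.to_dict(),
        "final_set": reduced,
        "n_cv_runs": ens_config.scheme.n_runs,
    }

    # -- holdout validation -------------------------------------------------
    feature_sets = {"full": list(features.columns), "reduced": reduced}
    if set(SPARSE_SET) <= set(features.columns):
        feature_sets["sparse"] = list(SPARSE_SET)
    xs = (xt - xt.mean()) / xt.std(ddof=1)
    tuned = {
        alg: tune_classifier(alg, xs.to_numpy(float), yt, seed=seeds["validation"], config=ens_config)
        for alg in ALGORITHMS
    }
    val = validate_feature_sets(
        xt, yt, xv, yv, feature_sets, tuned,
        n_runs=config.validation_runs, seed=seeds["validation"],
    )
    report["stages"]["validation"] = {"cluster_target": val.cells.to_dict("records")}

    # -- optional diagnosis-target rerun (selection contrast + validation) --
    diag_y = (diagnosis == "normosmia").astype(int) if diagnosis is not None else None
    diag_ok = diag_y is not None and np.bincount(diag_y, minlength=2).min() >= 10
    if config.diagnosis_target and diag_ok:
        xt_d, xv_d, yt_d, yv_d = holdout_split(
            features, diag_y, fraction=config.holdout_fraction, seed=seeds["diagnosis"]
        )
        matrix_d = run_feature_selection_ensemble(xt_d, yt_d, olf_cols, config=ens_config)
        ensemble_consolidate(matrix_d)
        contrast = target_contrast(matrix.sum_score, matrix_d.sum_score)
        xs_d = (xt_d - xt_d.mean()) / xt_d.std(ddof=1)
        tuned_d = {
            alg: tune_classifier(alg, xs_d.to_numpy(float), yt_d,
                                 seed=seeds["diagnosis"], config=ens_config)
            for alg in ALGORITHMS
        }
        feature_sets_d = dict(feature_sets, reduced=matrix.final_set)
        val_d = validate_feature_sets(
            xt_d, yt_d, xv_d, yv_d, feature_sets_d, tuned_d,
            n_runs=config.validation_runs, seed=seeds["diagnosis"],
        )
        report["stages"]["selection"]["diagnosis_sum_score"] = matrix_d.sum_score.to_dict()
        report["stages"]["selection"]["target_contrast"] = contrast.to_dict()
        report["stages"]["validation"]["diagnosis_target"] = val_d.cells.to_dict("records")

    # -- artifacts ----------------------------------------------------------
    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.write_csv(outdir / "cohort_preprocessed.csv", outdir / "cohort_preprocessed.yaml")
        pd.DataFrame({"cluster": cluster_labels}, index=table.subject_ids).to_csv(
            outdir / "cluster_labels.csv"
        )
        comparison.per_variable.to_csv(outdir / "group_stats.csv")
        matrix.to_table().to_csv(outdir / "selection_table.csv")
        val.cells.to_csv(outdir / "validation.csv", index=False)
        corr = table.values.corr(method="pearson")
        corr.to_csv(outdir / "correlations.csv")
        (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
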