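"""Cross-validated feature-selection ensemble with ABC consolidation.

Seventeen selection approaches are combined: PCA-based variable importance,
Cohen's d effect sizes, and five model-based selectors (SelectKBest on the
one-way F statistic, SelectFromModel, recursive feature elimination, and
forward/backward greedy sequential selection) each run with three tuned
classifiers (linear SVM, random forest, logistic regression).  The
model-based selectors run inside a repeated stratified k-fold scheme
(5 splits x 20 repeats = 100 runs at study scale) and record how often each
variable is selected; per method, computed ABC analysis of the counts (or of
the importance magnitudes for the two model-free methods) yields that
method's "A" set.  The per-variable sum of A-memberships across all 17
methods is itself ABC-categorized, and the final reduced feature set is the
"A" set of that sum score.

Because greedy sequential selection wrapped around a random forest is
expensive, an explicit desk-scale profile (``EnsembleConfig.fast()``) with
fewer CV runs, shallower internal CV, a coarser RFE step and a smaller
forest grid is provided for simulation studies; the study-scale defaults
remain the contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE, SelectKBest, f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import (
    GridSearchCV,
    RepeatedStratifiedKFold,
    StratifiedKFold,
    cross_val_score,
    train_test_split,
)
from sklearn.pipeline import Pipeline
from sklearn.svm import LinearSVC

from .abc_analysis import abc_set_a
from .cohort import CohortTable
from .group_stats import cohens_d
from .structure import pca_project, pca_variable_importance, retain_components

ALGORITHMS = ("SVM", "RF", "LogReg")
SELECTORS = ("SKB", "SFM", "RFE", "SFSf", "SFSb")
MODEL_FREE_METHODS = ("PCA", "CohensD")
METHODS = MODEL_FREE_METHODS + tuple(f"{s}_{a}" for s in SELECTORS for a in ALGORITHMS)

_C_GRID = np.logspace(-3, 3, 7)


@dataclass(frozen=True)
class CVScheme:
    """Repeated stratified k-fold scheme (study scale: 5 x 20 = 100 runs)."""

    n_splits: int = 5
    n_repeats: int = 20
    seed: int = 0

    @property
    def n_runs(self) -> int:
        return self.n_splits * self.n_repeats


@dataclass(frozen=True)
class EnsembleConfig:
    scheme: CVScheme = CVScheme()
    tune_cv: int = 5  # folds for hyperparameter and SelectKBest k grids
    sfs_cv: int = 5  # internal CV folds scoring greedy SFS candidates
    sfs_runs: int | None = None  # cap on CV runs for the SFS selectors
    sfs_max_moves: int | None = None  # cap on greedy SFS add/remove steps
    rfe_step: int = 1
    skb_k_step: int = 1  # stride of the SelectKBest k grid
    rf_n_estimators: tuple[int, ...] = (200, 100)
    rf_max_depth: tuple = (10, 5, None)
    sfs_tol: float = 1e-4

    @classmethod
    def fast(cls, seed: int = 0) -> "EnsembleConfig":
        """Desk-scale profile for simulation studies (see module docs)."""
        return cls(
            scheme=CVScheme(n_splits=5, n_repeats=1, seed=seed),
            tune_cv=3, sfs_cv=2, sfs_runs=1, sfs_max_moves=6, rfe_step=4,
            skb_k_step=2, rf_n_estimators=(30,), rf_max_depth=(10, 5),
        )


# ---------------------------------------------------------------------------
# splits and tuning
# ---------------------------------------------------------------------------

def holdout_split(
    table: CohortTable | pd.DataFrame,
    labels,
    fraction: float = 0.2,
    seed: int = 0,
):
    """Stratified holdout: set ``fraction`` of each group aside for validation.

    Returns (train_values, validation_values, train_labels, validation_labels).
    The validation part is meant to stay untouched until final testing.
    """
    values = table.values if isinstance(table, CohortTable) else table
    labels = np.asarray(labels)
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    counts = np.unique(labels, return_counts=True)[1]
    if np.any(counts * fraction < 1):
        raise ValueError("a group is too small to stratify the holdout")
    return train_test_split(
        values, labels, test_size=fraction, stratify=labels, random_state=seed
    )


def _base_estimator(algorithm: str, seed: int):
    if algorithm == "SVM":
        return LinearSVC(max_iter=20000, random_state=seed)
    if algorithm == "RF":
        return RandomForestClassifier(random_state=seed)
    if algorithm == "LogReg":
        return LogisticRegression(max_iter=5000, random_state=seed)
    raise ValueError(f"unknown algorithm {algorithm!r}")


def _param_grid(algorithm: str, config: EnsembleConfig):
    if algorithm == "SVM":
        # LASSO (L1) listed first: preferred on ties, matching the tuned outcome
        return [
            {"penalty": ["l1"], "dual": [False], "C": list(_C_GRID)},
            {"penalty": ["l2"], "dual": [False], "C": list(_C_GRID)},
        ]
    if algorithm == "LogReg":
        # Ridge (l1_ratio=0) with newton-cg first
        return [
            {"l1_ratio": [0.0], "solver": ["newton-cg"], "C": list(_C_GRID)},
            {"l1_ratio": [1.0], "solver": ["saga"], "C": list(_C_GRID)},
        ]
    if algorithm == "RF":
        return [{
            "max_depth": list(config.rf_max_depth),
            "n_estimators": list(config.rf_n_estimators),
        }]
    raise ValueError(f"unknown algorithm {algorithm!r}")


def tune_classifier(
    algorithm: str, x, y, seed: int = 0, config: EnsembleConfig | None = None
):
    """5-fold grid-search tuning by balanced accuracy.

    Linear models search penalty type (LASSO/Ridge) and strength; forests
    search tree count and depth.  Returns an unfitted estimator carrying the
    winning hyperparameters (ties resolve to the first grid entry, so the
    preferred conventions lead the grids).
    """
    config = config or EnsembleConfig()
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("training data must contain both classes")
    cv = StratifiedKFold(config.tune_cv, shuffle=True, random_state=seed)
    search = GridSearchCV(
        _base_estimator(algorithm, seed),
        _param_grid(algorithm, config),
        scoring="balanced_accuracy",
        cv=cv,
        n_jobs=None,
    )
    search.fit(np.asarray(x, dtype=float), y)
    return clone(search.best_estimator_)


# ---------------------------------------------------------------------------
# per-method selection counts
# ---------------------------------------------------------------------------

def _importances(fitted) -> np.ndarray:
    if hasattr(fitted, "feature_importances_"):
        return np.asarray(fitted.feature_importances_, dtype=float)
    if hasattr(fitted, "coef_"):
        return np.abs(np.asarray(fitted.coef_, dtype=float)).ravel()
    raise ValueError(f"{type(fitted).__name__} exposes no usable importances for SFM")


def _tune_skb_k(estimator, x, y, config: EnsembleConfig, seed: int) -> int:
    d = x.shape[1]
    cv = StratifiedKFold(config.tune_cv, shuffle=True, random_state=seed)
    best_k, best_score = 1, -np.inf
    for k in range(1, d + 1, config.skb_k_step):
        pipe = Pipeline([("skb", SelectKBest(f_classif, k=k)), ("clf", clone(estimator))])
        score = cross_val_score(pipe, x, y, cv=cv, scoring="balanced_accuracy").mean()
        if score > best_score + 1e-12:
            best_k, best_score = k, score
    return best_k


def _greedy_sfs(
    estimator, x, y, forward: bool, cv_folds: int, seed: int, tol: float,
    max_moves: int | None = None,
) -> np.ndarray:
    """Greedy add (forward, from empty) / remove (backward, from full) of the
    feature maximizing CV balanced accuracy; stops when the best move no
    longer improves the score by more than ``tol`` (or after ``max_moves``)."""
    d = x.shape[1]
    cv = StratifiedKFold(cv_folds, shuffle=True, random_state=seed)

    def score(feats: list[int]) -> float:
        return cross_val_score(
            clone(estimator), x[:, feats], y, cv=cv, scoring="balanced_accuracy"
        ).mean()

    selected = [] if forward else list(range(d))
    current = -np.inf if forward else score(selected)
    moves = 0
    while max_moves is None or moves < max_moves:
        pool = [f for f in range(d) if f not in selected] if forward else list(selected)
        if not pool or (not forward and len(selected) <= 1):
            break
        best_f, best_s = None, current
        for f in pool:
            trial = selected + [f] if forward else [g for g in selected if g != f]
            s = score(trial)
            if s > best_s + tol:
                best_f, best_s = f, s
        if best_f is None:
            break
        selected = selected + [best_f] if forward else [g for g in selected if g != best_f]
        current = best_s
        moves += 1
    support = np.zeros(d, dtype=bool)
    support[selected] = True
    return support


def run_selection_method(
    selector: str,
    estimator,
    x,
    y,
    config: EnsembleConfig | None = None,
    skb_k: int | None = None,
) -> np.ndarray:
    """Per-variable selection counts for one selector/classifier pair over the
    repeated stratified CV scheme."""
    config = config or EnsembleConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    d = x.shape[1]
    scheme = config.scheme

    if selector == "SKB" and skb_k is None:
        skb_k = _tune_skb_k(estimator, x, y, config, seed=scheme.seed)
    if selector == "SFM":
        _importances(clone(estimator).fit(x, y))  # reject estimators without importances

    rskf = RepeatedStratifiedKFold(
        n_splits=scheme.n_splits, n_repeats=scheme.n_repeats, random_state=scheme.seed
    )
    max_runs = config.sfs_runs if selector in ("SFSf", "SFSb") and config.sfs_runs else None
    counts = np.zeros(d)
    for run, (train_idx, _) in enumerate(rskf.split(x, y)):
        if max_runs is not None and run >= max_runs:
            break
        xt, yt = x[train_idx], y[train_idx]
        if selector == "SKB":
            support = SelectKBest(f_classif, k=skb_k).fit(xt, yt).get_support()
        elif selector == "SFM":
            imp = _importances(clone(estimator).fit(xt, yt))
            support = imp >= imp.mean()
        elif selector == "RFE":
            rfe = RFE(clone(estimator), n_features_to_select=d // 2, step=config.rfe_step)
            support = rfe.fit(xt, yt).support_
        elif selector in ("SFSf", "SFSb"):
            support = _greedy_sfs(
                estimator, xt, yt, forward=(selector == "SFSf"),
                cv_folds=config.sfs_cv, seed=scheme.seed + run, tol=config.sfs_tol,
                max_moves=config.sfs_max_moves,
            )
        else:
            raise ValueError(f"unknown selector {selector!r}")
        counts += support
    return counts


def consolidate_method(values) -> np.ndarray:
    """ABC "A" set of a nonnegative count/importance vector (item indices)."""
    v = np.asarray(values, dtype=float)
    if np.all(v == 0):
        raise ValueError("all-zero vector: nothing was ever selected")
    return abc_set_a(v)


# ---------------------------------------------------------------------------
# the full ensemble
# ---------------------------------------------------------------------------

@dataclass
class SelectionMatrix:
    """17 methods x variables record of the ensemble (Table-1-shaped)."""

    variables: list[str]
    counts: pd.DataFrame  # per model-based method: CV selection counts
    importances: pd.DataFrame  # PCA / CohensD importance magnitudes
    a_membership: pd.DataFrame  # 17 methods x variables booleans
    final_set: list[str] = field(default_factory=list)

    @property
    def sum_score(self) -> pd.Series:
        return self.a_membership.sum(axis=0)

    def to_table(self) -> pd.DataFrame:
        """Variables x methods binary table with Sum and Final columns."""
        out = self.a_membership.T.astype(int)
        out.insert(0, "Sum", self.sum_score)
        out.insert(0, "Final", [v in self.final_set for v in out.index])
        return out


def ensemble_consolidate(matrix: SelectionMatrix) -> list[str]:
    """Final reduced set: ABC "A" of the per-variable sum of A-memberships."""
    missing = [m for m in METHODS if m not in matrix.a_membership.index]
    if missing:
        raise ValueError(f"ensemble rows missing: {missing}")
    sums = matrix.sum_score.to_numpy(dtype=float)
    final = [matrix.variables[i] for i in sorted(abc_set_a(sums))]
    matrix.final_set = final
    return final


def run_feature_selection_ensemble(
    x: pd.DataFrame,
    y,
    olfaction_columns: list[str],
    config: EnsembleConfig | None = None,
    tuned: dict | None = None,
) -> SelectionMatrix:
    """Run all 17 approaches on a training table and consolidate.

    ``x`` holds the (preprocessed) training features, olfaction variables and
    covariates alike; PCA importance is computed on the olfaction columns
    only, so covariates carry a structural zero in that row.  Features are
    z-scored internally for the model-based selectors.  ``tuned`` may carry
    pre-tuned estimators keyed by algorithm name.
    """
    config = config or EnsembleConfig()
    y = np.asarray(y)
    variables = list(x.columns)
    xs = (x - x.mean()) / x.std(ddof=1)
    xs_arr = xs.to_numpy(dtype=float)

    if tuned is None:
        tuned = {
            alg: tune_classifier(alg, xs_arr, y, seed=config.scheme.seed, config=config)
            for alg in ALGORITHMS
        }

    counts_rows, a_rows = {}, {}
    imp_rows = {}

    # model-free rows -----------------------------------------------------
    olf_idx = [variables.index(c) for c in olfaction_columns]
    z_olf = xs_arr[:, olf_idx]
    model = pca_project(z_olf)
    imp = pca_variable_importance(z_olf, model, retain_components(model))
    pca_imp = np.zeros(len(variables))
    pca_imp[olf_idx] = imp.absolute
    imp_rows["PCA"] = pca_imp
    a_olf = consolidate_method(imp.absolute)
    mask = np.zeros(len(variables), dtype=bool)
    mask[[olf_idx[i] for i in a_olf]] = True
    a_rows["PCA"] = mask

    d_vec = np.array([
        abs(cohens_d(x.iloc[y == np.unique(y)[0]][v], x.iloc[y == np.unique(y)[1]][v]))
        for v in variables
    ])
    imp_rows["CohensD"] = d_vec
    mask = np.zeros(len(variables), dtype=bool)
    mask[consolidate_method(d_vec)] = True
    a_rows["CohensD"] = mask

    # model-based rows ----------------------------------------------------
    skb_k = {
        alg: _tune_skb_k(tuned[alg], xs_arr, y, config, seed=config.scheme.seed)
        for alg in ALGORITHMS
    }
    for selector in SELECTORS:
        for alg in ALGORITHMS:
            name = f"{selector}_{alg}"
            counts = run_selection_method(
                selector, tuned[alg], xs_arr, y, config=config, skb_k=skb_k[alg]
            )
            counts_rows[name] = counts
            mask = np.zeros(len(variables), dtype=bool)
            mask[consolidate_method(counts)] = True
            a_rows[name] = mask

    matrix = SelectionMatrix(
        variables=variables,
        counts=pd.DataFrame(counts_rows, index=variables).T,
        importances=pd.DataFrame(imp_rows, index=variables).T,
        a_membership=pd.DataFrame(a_rows, index=variables).T.loc[list(METHODS)],
    )
    ensemble_consolidate(matrix)
    return matrix


def target_contrast(sums_a: pd.Series, sums_b: pd.Series) -> pd.Series:
    """Per-variable difference of ensemble sum scores between two targets
    (e.g. cluster labels minus olfactory diagnosis)."""
    if set(sums_a.index) != set(sums_b.index):
        raise ValueError("sum scores cover different variable sets")
    return sums_a - sums_b.reindex(sums_a.index)
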