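"""Holdout validation of reduced feature sets.

After feature selection, the question is whether the reduced (and an even
sparser two-variable) feature set still carries the cluster or diagnosis
signal into data never touched during selection.  Tuned classifiers are
re-fit on random stratified 80% subsets of the training data and scored on
random stratified 80% subsets of the holdout, over 100 runs; each
classifier x feature-set cell reports the median balanced accuracy with a
nonparametric 95% CI (2.5th-97.5th percentiles).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.model_selection import train_test_split


def balanced_accuracy(y_true, y_pred) -> float:
    """Mean of per-class recalls; 0.5 is chance for two classes."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    classes = np.unique(y_true)
    if classes.size < 2:
        raise ValueError("y_true must contain at least two classes")
    recalls = [np.mean(y_pred[y_true == c] == c) for c in classes]
    return float(np.mean(recalls))


@dataclass
class ValidationReport:
    """Table-2-shaped medians and nonparametric CIs per classifier x set."""

    cells: pd.DataFrame  # columns: classifier, feature_set, median, ci_lo, ci_hi, unstable
    n_runs: int

    def formatted(self) -> pd.DataFrame:
        """classifier x feature-set grid of 'median (lo-hi)' strings."""
        fmt = self.cells.assign(
            text=lambda d: d.apply(
                lambda r: f"{r['median']:.2f} ({r.ci_lo:.2f}-{r.ci_hi:.2f})", axis=1
            )
        )
        return fmt.pivot(index="classifier", columns="feature_set", values="text")


def validate_feature_sets(
    x_train: pd.DataFrame,
    y_train,
    x_val: pd.DataFrame,
    y_val,
    feature_sets: dict[str, list[str]],
    classifiers: dict[str, object],
    n_runs: int = 100,
    subsample: float = 0.8,
    seed: int = 0,
) -> ValidationReport:
    """Median balanced accuracy of each classifier on each feature set.

    Per run, a stratified ``subsample`` fraction of the training table is
    drawn to fit and a stratified ``subsample`` fraction of the validation
    table to score.  A cell is flagged unstable when a class goes missing
    from the scored subset in more than half of the runs.
    """
    y_train = np.asarray(y_train)
    y_val = np.asarray(y_val)
    if len(np.intersect1d(x_train.index, x_val.index)):
        raise ValueError("training and validation subjects overlap")
    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2**31 - 1, size=n_runs)

    mu = x_train.mean()
    sd = x_train.std(ddof=1).replace(0.0, 1.0)
    xt_all = (x_train - mu) / sd
    xv_all = (x_val - mu) / sd  # holdout scaled by training statistics

    rows = []
    for set_name, columns in feature_sets.items():
        missing = [c for c in columns if c not in x_train.columns]
        if missing:
            raise ValueError(f"feature set {set_name!r} names absent columns: {missing}")
        for clf_name, estimator in classifiers.items():
            scores, degenerate = [], 0
            for r in range(n_runs):
                rs = int(run_seeds[r])
                xt, _, yt, _ = train_test_split(
                    xt_all[columns], y_train, train_size=subsample,
                    stratify=y_train, random_state=rs,
                )
                xv, _, yv, _ = train_test_split(
                    xv_all[columns], y_val, train_size=subsample,
                    stratify=y_val, random_state=rs,
                )
                if np.unique(yv).size < 2:
                    degenerate += 1
                    continue
                model = clone(estimator).fit(xt.to_numpy(), yt)
                scores.append(balanced_accuracy(yv, model.predict(xv.to_numpy())))
            scores = np.asarray(scores)
            rows.append({
                "classifier": clf_name,
                "feature_set": set_name,
                "median": float(np.median(scores)),
                "ci_lo": float(np.percentile(scores, 2.5)),
                "ci_hi": float(np.percentile(scores, 97.5)),
                "unstable": degenerate > n_runs / 2,
            })
    return ValidationReport(cells=pd.DataFrame(rows), n_runs=n_runs)
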