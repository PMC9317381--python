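"""The 17-method feature-selection ensemble with ABC consolidation.

Sets 20% of each cluster aside as the validation sample, tunes the three
classifiers, runs the five model-based selectors per classifier plus PCA
importance and Cohen's d in repeated stratified CV, ABC-categorizes each
method's selection counts, and consolidates the per-variable sum of "A"
memberships into the reduced feature set.  Optionally reruns the ensemble
against the olfactory diagnosis and writes the per-variable sum-score
contrast (cluster minus diagnosis).
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

import olfphen as op
from olfphen.pipeline import derive_diagnosis
from olfphen.selection import CVScheme, EnsembleConfig

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--outdir", type=Path, default=Path("results/analysis"))
parser.add_argument("--study-scale", action="store_true",
                    help="100 CV runs per method instead of the desk-scale profile")
parser.add_argument("--skip-diagnosis", action="store_true")
args = parser.parse_args()

table = op.read_cohort_csv(args.outdir / "cohort_preprocessed.csv",
                           args.outdir / "cohort_preprocessed.yaml")
labels = pd.read_csv(args.outdir / "cluster_labels.csv", index_col=0)["cluster"].to_numpy()

config = (EnsembleConfig(scheme=CVScheme(seed=args.seed)) if args.study_scale
          else EnsembleConfig.fast(seed=args.seed))
xt, xv, yt, yv = op.holdout_split(table.values, labels, fraction=0.2, seed=args.seed)
pd.DataFrame({"holdout": table.subject_ids.isin(xv.index).astype(int)},
             index=table.subject_ids).to_csv(args.outdir / "holdout_mask.csv")

matrix = op.run_feature_selection_ensemble(xt, yt, table.olfaction_columns, config=config)
matrix.to_table().to_csv(args.outdir / "selection_table.csv")

print(f"CV scheme: {config.scheme.n_splits} splits x {config.scheme.n_repeats} repeats")
print("per-variable sum of ABC-'A' memberships across the 17 methods:")
print(matrix.sum_score.sort_values(ascending=False).head(8).to_string())
print(f"reduced feature set (ABC 'A' of the sum score): {matrix.final_set}")

if not args.skip_diagnosis:
    diagnosis = (derive_diagnosis(table) == "normosmia").astype(int)
    if np.bincount(diagnosis, minlength=2).min() >= 10:
        xt_d, _, yt_d, _ = op.holdout_split(table.values, diagnosis, 0.2, seed=args.seed)
        matrix_d = op.run_feature_selection_ensemble(
            xt_d, yt_d, table.olfaction_columns, config=config
        )
        contrast = op.target_contrast(matrix.sum_score, matrix_d.sum_score)
        contrast.rename("cluster_minus_diagnosis").to_csv(args.outdir / "target_contrast.csv")
        print("sum-score contrast (cluster target minus diagnosis target), "
              "positive = cluster-specific:")
        print(contrast.sort_values(ascending=False).head(6).to_string())
    else:
        print("too few impaired subjects for a diagnosis-target rerun")

(args.outdir / "selection.json").write_text(json.dumps({
    "final_set": matrix.final_set,
    "sum_score": matrix.sum_score.to_dict(),
    "n_cv_runs": config.scheme.n_runs,
}, indent=2))
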