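"""Validate the reduced and sparse feature sets on the held-out subjects.

Re-fits the tuned classifiers on random stratified 80% subsets of the
training sample and scores them on random 80% subsets of the untouched
holdout, 100 times, for the full (15 + age/sex/BMI), reduced (ensemble
final set) and sparse (raw PEA/EUG sorting scores) feature sets, with the
cluster and the olfactory-diagnosis targets.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

import olfphen as op
from olfphen.pipeline import SPARSE_SET, derive_diagnosis
from olfphen.selection import ALGORITHMS, EnsembleConfig

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--outdir", type=Path, default=Path("results/analysis"))
parser.add_argument("--runs", type=int, default=100)
args = parser.parse_args()

table = op.read_cohort_csv(args.outdir / "cohort_preprocessed.csv",
                           args.outdir / "cohort_preprocessed.yaml")
labels = pd.read_csv(args.outdir / "cluster_labels.csv", index_col=0)["cluster"].to_numpy()
final_set = json.loads((args.outdir / "selection.json").read_text())["final_set"]
feature_sets = {"full": list(table.values.columns), "reduced": final_set,
                "sparse": list(SPARSE_SET)}
config = EnsembleConfig.fast(seed=args.seed)

frames = []
targets = {"cluster": labels}
diagnosis = (derive_diagnosis(table) == "normosmia").astype(int)
if np.bincount(diagnosis, minlength=2).min() >= 10:
    targets["diagnosis"] = diagnosis

for target_name, y in targets.items():
    xt, xv, yt, yv = op.holdout_split(table.values, y, fraction=0.2, seed=args.seed)
    xs = (xt - xt.mean()) / xt.std(ddof=1)
    tuned = {alg: op.tune_classifier(alg, xs.to_numpy(float), yt,
                                     seed=args.seed, config=config)
             for alg in ALGORITHMS}
    report = op.validate_feature_sets(xt, yt, xv, yv, feature_sets, tuned,
                                      n_runs=args.runs, seed=args.seed + 1)
    frames.append(report.cells.assign(target=target_name))
    print(f"target = {target_name}: median balanced accuracy "
          f"(95% CI, {args.runs} runs)")
    print(report.formatted().to_string())

pd.concat(frames).to_csv(args.outdir / "validation.csv", index=False)
print(f"written to {args.outdir}/validation.csv")
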