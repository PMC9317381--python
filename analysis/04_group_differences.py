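"""Supervised comparison of the detected clusters.

Mann-Whitney U tests with Bonferroni correction and Cohen's d over the 15
olfaction variables plus age and BMI, chi-square tests for sex and for the
olfactory diagnosis (derived from the TDI composite) against cluster
membership.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import olfphen as op
from olfphen.pipeline import derive_diagnosis

parser = argparse.ArgumentParser()
parser.add_argument("--outdir", type=Path, default=Path("results/analysis"))
args = parser.parse_args()

table = op.read_cohort_csv(args.outdir / "cohort_preprocessed.csv",
                           args.outdir / "cohort_preprocessed.yaml")
labels = pd.read_csv(args.outdir / "cluster_labels.csv", index_col=0)["cluster"].to_numpy()
diagnosis = derive_diagnosis(table)

report = op.compare_groups(table, labels, diagnosis=diagnosis, yates=True)
report.per_variable.to_csv(args.outdir / "group_differences.csv")
report.categorical.to_csv(args.outdir / "group_differences_categorical.csv", index=False)

dx_counts = dict(zip(*np.unique(diagnosis, return_counts=True)))
print(f"olfactory diagnoses in the cohort: {dx_counts}")
tiers = report.per_variable.tier.value_counts().to_dict()
print(f"{report.n_tests} tests, Bonferroni threshold "
      f"{report.bonferroni_threshold:.4f}; significance tiers: {tiers}")
top = report.per_variable.reindex(
    report.per_variable.cohens_d.abs().sort_values(ascending=False).index
).head(6)
print("largest effects (Cohen's d, positive = larger in cluster 1):")
print(top[["cohens_d", "p", "tier"]].round(4).to_string())
for _, row in report.categorical.iterrows():
    print(f"{row['comparison']}: chi2 = {row.chi2:.3f}, p = {row.p:.4f} "
          f"(Yates = {row.yates})")
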