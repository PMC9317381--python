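"""Supervised comparison of detected subgroups.

Mann-Whitney U (exact permutation p for small samples, tie-corrected normal
approximation otherwise) and chi-square tests per variable, Cohen's d effect
sizes with the convention that positive d means larger values in the second
(cluster 1) group, and Bonferroni correction over the test battery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable

EXACT_MWU_LIMIT = 400  # exact permutation p when n1 * n2 <= this


def _exact_rank_sum_p(ranks: np.ndarray, n1: int, obs_sum: float) -> float:
    """Exact two-sided permutation p for the rank sum of group 1.

    Dynamic programme over the (doubled, hence integer) midranks, counting
    subsets of size n1 by rank sum; handles ties exactly.  Two-sidedness uses
    the symmetry of the permutation distribution around its mean.
    """
    doubled = np.round(ranks * 2).astype(int)
    total = doubled.sum()
    # counts[j][s] = number of size-j subsets with doubled-rank sum s
    counts = [np.zeros(total + 1, dtype=float) for _ in range(n1 + 1)]
    counts[0][0] = 1.0
    for r in doubled:
        for j in range(n1 - 1, -1, -1):
            nz = np.nonzero(counts[j])[0]
            counts[j + 1][nz + r] += counts[j][nz]
    dist = counts[n1]
    n_total = dist.sum()
    sums = np.arange(total + 1)
    mean = float((dist * sums).sum() / n_total)
    dev = abs(obs_sum * 2 - mean)
    p = dist[np.abs(sums - mean) >= dev - 1e-9].sum() / n_total
    return float(min(1.0, p))


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann-Whitney U (for the first group, midrank ties) with two-sided p.

    Small samples (n1*n2 <= 400) get an exact permutation p from the tie-aware
    rank-sum distribution; larger samples use the tie-corrected normal
    approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    n1, n2 = x.size, y.size
    ranks = stats.rankdata(np.concatenate([x, y]))
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    if n1 * n2 <= EXACT_MWU_LIMIT:
        # run the DP over the smaller group; the two-sided p is the same
        if n1 <= n2:
            p = _exact_rank_sum_p(ranks, n1, r1)
        else:
            p = _exact_rank_sum_p(ranks, n2, ranks[n1:].sum())
    else:
        p = float(stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue)
    return float(u1), p


def chi_square_2x2(table, yates: bool) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 count table, optional Yates correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(t < 0) or np.any(t != np.round(t)):
        raise ValueError("counts must be nonnegative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero row/column margin")
    res = stats.chi2_contingency(t, correction=yates)
    return float(res.statistic), float(res.pvalue)


def cohens_d(x, y) -> float:
    """Cohen's d = (mean(y) - mean(x)) / pooled SD; positive = larger in the
    second (cluster 1) group."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both groups need >= 2 values")
    n1, n2 = x.size, y.size
    pooled_var = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if pooled_var == 0:
        raise ValueError("zero pooled variance")
    return float((y.mean() - x.mean()) / np.sqrt(pooled_var))


@dataclass
class ComparisonReport:
    """Per-variable U/p/d with significance tiers, plus categorical chi-squares."""

    per_variable: pd.DataFrame  # columns: U, p, cohens_d, tier
    categorical: pd.DataFrame  # columns: chi2, p, yates
    alpha: float = 0.05
    n_tests: int = 18
    contingency_tables: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def bonferroni_threshold(self) -> float:
        return self.alpha / self.n_tests


def _tier(p: float, alpha: float, n_tests: int) -> str:
    if p < alpha / n_tests:
        return "bonferroni"
    return "nominal" if p < alpha else "ns"


def compare_groups(
    table: CohortTable,
    labels,
    diagnosis=None,
    alpha: float = 0.05,
    yates: bool = True,
) -> ComparisonReport:
    """Full two-group battery over olfaction variables plus age/sex/BMI.

    Numeric variables get Mann-Whitney U, two-sided p, and Cohen's d
    (positive = larger in group 1); sex (and the optional diagnosis vector)
    get 2x2 chi-square tests of their cross-tabulation with the grouping,
    Yates-corrected by default.  Bonferroni uses the total battery size.
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size != 2:
        raise ValueError("exactly two groups required")
    g0, g1 = labels == groups[0], labels == groups[1]

    numeric_cols = [c for c in table.values.columns if c != "sex"]
    n_tests = len(numeric_cols) + ("sex" in table.values.columns)
    rows, tables = [], {}
    for col in numeric_cols:
        x = table.values.loc[g0, col].dropna().to_numpy()
        y = table.values.loc[g1, col].dropna().to_numpy()
        u, p = mann_whitney_u(x, y)
        rows.append({"variable": col, "U": u, "p": p,
                     "cohens_d": cohens_d(x, y), "tier": _tier(p, alpha, n_tests)})
    per_variable = pd.DataFrame(rows).set_index("variable")

    cat_rows = []
    if "sex" in table.values.columns:
        sex = table.values["sex"].to_numpy()
        tab = np.array([
            [np.sum((g == 1) & (sex == 1)), np.sum((g == 1) & (sex == 0))]
            for g in (g0, g1)
        ])
        chi2, p = chi_square_2x2(tab, yates=yates)
        cat_rows.append({"comparison": "sex_by_group", "chi2": chi2, "p": p, "yates": yates})
        tables["sex_by_group"] = tab
    if diagnosis is not None:
        diagnosis = np.asarray(diagnosis)
        cats = np.unique(diagnosis)
        if cats.size == 2:
            tab = np.array([
                [np.sum(g & (diagnosis == c)) for c in cats] for g in (g0, g1)
            ])
            chi2, p = chi_square_2x2(tab, yates=yates)
            cat_rows.append({"comparison": "diagnosis_by_group", "chi2": chi2, "p": p, "yates": yates})
            tables["diagnosis_by_group"] = tab
    categorical = pd.DataFrame(cat_rows)

    return ComparisonReport(per_variable=per_variable, categorical=categorical,
                            alpha=alpha, n_tests=n_tests, contingency_tables=tables)
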