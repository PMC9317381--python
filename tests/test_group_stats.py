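"""Group comparison battery: Mann-Whitney U (with an enumeration oracle),
chi-square tests against the published statistics, Cohen's d, Bonferroni
calibration."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats

import olfphen as op
from olfphen.simulate import OLFACTION_VARIABLES


def brute_force_mwu(x, y):
    """Independent oracle: U by pairwise comparison, p by enumerating every
    assignment of the pooled values to the two groups."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)

    def u_of(first_idx):
        first = pooled[list(first_idx)]
        rest = pooled[[i for i in range(n) if i not in first_idx]]
        gt = sum((a > b) for a in first for b in rest)
        eq = sum((a == b) for a in first for b in rest)
        return gt + 0.5 * eq

    u_obs = u_of(tuple(range(n1)))
    mu = n1 * (n - n1) / 2.0
    us = [u_of(c) for c in combinations(range(n), n1)]
    p = np.mean([abs(u - mu) >= abs(u_obs - mu) - 1e-9 for u in us])
    return u_obs, p


class TestMannWhitney:
    def test_complete_separation(self):
        u, p = op.mann_whitney_u([1, 2, 3], [10, 11, 12])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-9)  # 2/C(6,3)=2/20

    def test_identical_multisets(self):
        u, p = op.mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4])
        assert u == 4 * 4 / 2
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_p_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 6, 5).astype(float)  # ties likely
        y = rng.integers(0, 6, 5).astype(float)
        u_ref, p_ref = brute_force_mwu(x, y)
        u, p = op.mann_whitney_u(x, y)
        assert u == pytest.approx(u_ref)
        assert p == pytest.approx(p_ref, abs=1e-12)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=6), rng.normal(size=7)
        _, p = op.mann_whitney_u(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert p == pytest.approx(ref, abs=1e-12)

    def test_rejects_empty_group(self):
        with pytest.raises(ValueError):
            op.mann_whitney_u([], [1.0])


class TestChiSquare:
    @pytest.mark.parametrize(
        "table, yates, chi2, p",
        [
            # cohort composition vs the general population
            ([[117, 18], [82, 18]], False, 0.964, 0.3261),
            # sex by olfactory diagnosis
            ([[73, 44], [10, 8]], True, 0.0869, 0.768),
            # sex by detected cluster
            ([[56, 24], [27, 28]], True, 5.166, 0.023),
        ],
    )
    def test_published_statistics(self, table, yates, chi2, p):
        got_chi2, got_p = op.chi_square_2x2(table, yates=yates)
        assert got_chi2 == pytest.approx(chi2, abs=5e-4)
        assert got_p == pytest.approx(p, abs=5e-4)

    def test_transpose_and_swap_invariance(self):
        t = np.array([[12, 5], [7, 20]])
        base = op.chi_square_2x2(t, yates=True)
        assert op.chi_square_2x2(t.T, yates=True) == pytest.approx(base)
        assert op.chi_square_2x2(t[::-1, ::-1], yates=True) == pytest.approx(base)

    def test_rejects_bad_tables(self):
        with pytest.raises(ValueError):
            op.chi_square_2x2([[1, 2, 3], [4, 5, 6]], yates=True)
        with pytest.raises(ValueError):
            op.chi_square_2x2([[0, 0], [3, 4]], yates=True)
        with pytest.raises(ValueError):
            op.chi_square_2x2([[1.5, 2], [3, 4]], yates=True)


class TestCohensD:
    def test_identical_groups(self):
        x = np.arange(10.0)
        assert op.cohens_d(x, x) == 0.0

    def test_unit_shift_large_n(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 50000)
        y = rng.normal(1, 1, 50000)
        assert op.cohens_d(x, y) == pytest.approx(1.0, abs=0.03)

    def test_small_sample_matches_direct_formula(self):
        x = np.array([1.0, 2.0, 4.0])
        y = np.array([3.0, 5.0, 6.0, 7.0])
        pooled = np.sqrt((2 * x.var(ddof=1) + 3 * y.var(ddof=1)) / 5)
        assert op.cohens_d(x, y) == pytest.approx((y.mean() - x.mean()) / pooled, abs=1e-12)

    def test_sign_convention(self):
        # positive d = larger in the second (cluster 1) group
        assert op.cohens_d([0.0, 0.1, -0.1], [5.0, 5.1, 4.9]) > 0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            op.cohens_d([1.0, 1.0], [1.0, 1.0])


class TestCompareGroups:
    def test_planted_effects_reach_bonferroni(self, preprocessed):
        table, _, labels = preprocessed
        report = op.compare_groups(table, labels)
        assert report.n_tests == 18
        assert report.bonferroni_threshold == pytest.approx(0.05 / 18)
        for var in ("score_pea", "score_eug"):
            assert report.per_variable.loc[var, "tier"] == "bonferroni"
        # sorting errors are larger in the cluster with the worse sense of smell
        d_pea = report.per_variable.loc["score_pea", "cohens_d"]
        d_dis = report.per_variable.loc["olfdis", "cohens_d"]
        assert d_pea * d_dis < 0  # opposite directions

    def test_null_nominal_count_calibrated(self):
        zero = {v: 0.0 for v in OLFACTION_VARIABLES}
        counts = []
        for seed in range(60):
            t, labels = op.generate_cohort(
                op.SyntheticConfig(seed=seed + 500, missing_fraction=0.0,
                                   effect_sizes=zero, demographic_shifts=False)
            )
            rep = op.compare_groups(t, labels)
            counts.append((rep.per_variable.p < 0.05).sum())
        # expectation is 17 numeric tests x 0.05 = 0.85 nominal hits
        assert 0.3 < np.mean(counts) < 1.6

    def test_single_group_rejected(self, cohort):
        table, _ = cohort
        with pytest.raises(ValueError):
            op.compare_groups(table, np.zeros(table.n_subjects))
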