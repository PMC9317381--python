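"""PCA projection, component retention, variable importance, k-means with
silhouette-driven k selection, bootstrap stability, ARI."""

import itertools
import warnings

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import olfphen as op
from olfphen.structure import PCAModel, _pam

from conftest import blobs


def _z(x):
    return (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)


class TestPCA:
    def test_perfectly_correlated_pair(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=500)
        z = _z(np.column_stack([a, 2 * a + 1]))
        model = op.pca_project(z)
        assert model.eigenvalues[0] == pytest.approx(2.0, abs=1e-9)
        assert model.n_components == 1  # the zero eigenvalue is truncated

    def test_independent_columns_have_unit_eigenvalues(self):
        z = _z(np.random.default_rng(1).normal(size=(10000, 5)))
        model = op.pca_project(z)
        assert np.all(np.abs(model.eigenvalues - 1.0) < 0.1)
        assert model.explained_fraction.sum() == pytest.approx(1.0)

    def test_sign_fixing_makes_output_deterministic(self):
        z = _z(np.random.default_rng(2).normal(size=(200, 4)))
        a, b = op.pca_project(z), op.pca_project(z.copy())
        assert np.allclose(a.scores, b.scores)
        for j in range(a.loadings.shape[1]):
            assert a.loadings[np.argmax(np.abs(a.loadings[:, j])), j] > 0

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            op.pca_project(np.array([[1.0, np.nan], [0.0, 1.0]]))


class TestRetention:
    def _model(self, eigenvalues):
        ev = np.asarray(eigenvalues, dtype=float)
        return PCAModel(loadings=np.eye(len(ev)), eigenvalues=ev,
                        explained_fraction=ev / ev.sum(), scores=np.zeros((3, len(ev))))

    def test_kaiser_guttman_threshold(self):
        assert op.retain_components(self._model([3.2, 1.01, 0.99, 0.5])) == 2

    def test_fallback_with_warning(self):
        with pytest.warns(UserWarning):
            assert op.retain_components(self._model([0.9, 0.6])) == 1

    def test_two_factor_data_retains_two(self):
        rng = np.random.default_rng(3)
        factors = rng.normal(size=(2000, 2))
        weights = np.array([[1, 1, 1, 0, 0, 0], [0, 0, 0, 1, 1, 1]], dtype=float)
        x = factors @ weights + 0.4 * rng.normal(size=(2000, 6))
        assert op.retain_components(op.pca_project(_z(x))) == 2


class TestVariableImportance:
    def test_planted_signal_pair_dominates(self):
        # correlation PCA sees cluster signal through the correlation the
        # shared shift induces between the carrying variables
        rng = np.random.default_rng(4)
        labels = np.repeat([0, 1], 100)
        x = rng.normal(size=(200, 6))
        x[:, 2] += labels * 3.0
        x[:, 5] += labels * 3.0
        model = op.pca_project(_z(x))
        imp = op.pca_variable_importance(_z(x), model, 1)
        assert set(np.argsort(imp.absolute)[-2:]) == {2, 5}

    def test_exchangeable_variables_equal_importance_in_distribution(self):
        # per-seed the within-component z-scoring amplifies sampling noise,
        # but symmetry holds in distribution: seed-averaged importances agree
        sums = np.zeros(4)
        for seed in range(60):
            rng = np.random.default_rng(100 + seed)
            latent = rng.normal(size=(400, 1))
            x = latent + rng.normal(size=(400, 4))
            model = op.pca_project(_z(x))
            sums += op.pca_variable_importance(_z(x), model, 1).absolute
        assert sums.max() / sums.min() < 1.4

    def test_sign_flip_invariance(self):
        z = _z(np.random.default_rng(6).normal(size=(300, 5)))
        model = op.pca_project(z)
        flipped = PCAModel(loadings=-model.loadings, eigenvalues=model.eigenvalues,
                           explained_fraction=model.explained_fraction,
                           scores=-model.scores)
        a = op.pca_variable_importance(z, model, 3).absolute
        b = op.pca_variable_importance(z, flipped, 3).absolute
        assert np.allclose(a, b)

    def test_full_space_variant_and_bounds(self):
        z = _z(np.random.default_rng(7).normal(size=(100, 5)))
        model = op.pca_project(z)
        full = op.pca_variable_importance(z, model, model.n_components)
        assert np.all(full.absolute >= 0)
        with pytest.raises(ValueError):
            op.pca_variable_importance(z, model, model.n_components + 1)


class TestKMeans:
    def test_separated_blobs_recovered_exactly(self):
        x, y = blobs(separation=10.0, seed=8)
        sol = op.kmeans_cluster(x, 2, seed=0)
        assert op.adjusted_rand_index(y, sol.labels) == pytest.approx(1.0)
        assert -1 <= sol.silhouettes.min() and sol.silhouettes.max() <= 1
        assert sol.mean_silhouette > 0.8

    def test_determinism_and_bounds(self):
        x, _ = blobs(seed=9)
        a = op.kmeans_cluster(x, 3, seed=1)
        b = op.kmeans_cluster(x, 3, seed=1)
        assert np.array_equal(a.labels, b.labels)
        with pytest.raises(ValueError):
            op.kmeans_cluster(x[:4], 4, seed=0)
        small = op.kmeans_cluster(x[:5], 4, seed=0)  # k = n - 1 is legal
        assert np.unique(small.labels).size == 4


class TestSelectK:
    @pytest.mark.parametrize("k_true", [2, 4])
    def test_recovers_planted_k(self, k_true):
        x, _ = blobs(n_per=40, k=k_true, separation=12.0, seed=10 + k_true)
        best_k, _ = op.select_k_by_silhouette(x, seed=0)
        assert best_k == k_true

    def test_noise_has_low_silhouette(self):
        x = np.random.default_rng(11).normal(size=(135, 6))
        best_k, sols = op.select_k_by_silhouette(x, seed=0)
        assert sols[best_k].mean_silhouette < 0.2


class TestBootstrapStability:
    def test_blobs_are_stable(self):
        x, y = blobs(n_per=60, separation=10.0, seed=12)
        sol = op.kmeans_cluster(x, 2, seed=0)
        report = op.bootstrap_stability(x, sol.labels, n_runs=20, seed=0)
        assert report.mean_ari > 0.95
        assert report.n_runs == 20

    def test_noise_is_much_less_stable(self):
        # k-means directions on pure noise retain some stability at this n;
        # the point is the wide gap to the separated-blob case
        aris = []
        for seed in range(5):
            x = np.random.default_rng(seed).normal(size=(135, 6))
            sol = op.kmeans_cluster(x, 2, seed=seed)
            aris.append(op.bootstrap_stability(x, sol.labels, n_runs=10, seed=seed).mean_ari)
        assert np.mean(aris) < 0.6

    def test_identical_partitions_have_unit_ari(self):
        labels = np.repeat([0, 1, 2], 10)
        assert op.adjusted_rand_index(labels, labels) == pytest.approx(1.0)


class TestCompareClusterers:
    def test_kmeans_leads_on_spherical_blobs(self):
        x, _ = blobs(n_per=50, separation=10.0, seed=13)
        table = op.compare_clusterers(x, 2, seed=0)
        assert set(table) == {"kmeans", "ward", "pam"}
        assert table["kmeans"] >= table["ward"] - 1e-9
        assert table["kmeans"] >= table["pam"] - 1e-9

    def test_deterministic(self):
        x, _ = blobs(seed=14)
        assert op.compare_clusterers(x, 2, seed=3) == op.compare_clusterers(x, 2, seed=3)

    def test_pam_minimizes_locally(self):
        x, y = blobs(n_per=30, separation=8.0, seed=15)
        labels = _pam(x, 2, seed=0)
        assert adjusted_rand_score(y, labels) == pytest.approx(1.0)


class TestARI:
    def test_label_renaming_invariance(self):
        a = np.array([0, 0, 1, 1, 2, 2])
        b = np.array([5, 5, 9, 9, 7, 7])
        assert op.adjusted_rand_index(a, b) == pytest.approx(1.0)

    def test_independent_partitions_near_zero(self):
        rng = np.random.default_rng(16)
        a = rng.integers(0, 3, 1000)
        b = rng.integers(0, 3, 1000)
        assert abs(op.adjusted_rand_index(a, b)) < 0.05

    def test_agrees_with_reference_implementation(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            n = rng.integers(4, 30)
            a = rng.integers(0, 4, n)
            b = rng.integers(0, 4, n)
            assert op.adjusted_rand_index(a, b) == pytest.approx(
                adjusted_rand_score(a, b), abs=1e-12
            )

    def test_exhaustive_small_partitions(self):
        # every pair of binary labelings of 6 points
        for a in itertools.product([0, 1], repeat=6):
            b = (np.array(a) + 1) % 2
            assert op.adjusted_rand_index(a, b) == pytest.approx(1.0) or len(set(a)) == 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            op.adjusted_rand_index([0, 1], [0, 1, 1])
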