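"""Unsupervised structure detection in the olfaction feature space.

PCA of the z-standardized olfaction variables with Kaiser-Guttman component
retention (eigenvalues > 1); a variance-weighted variable importance derived
from the variable-component association matrix; k-means clustering on the
retained component scores with the mean silhouette width steering the choice
of k in 2..5; bootstrap stability of the chosen solution (silhouette and
adjusted Rand index over resampling runs); and an apples-to-apples silhouette
comparison against Ward agglomeration and partitioning around medoids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.metrics import silhouette_samples

KMEANS_RESTARTS = 25
KMEANS_TOL = 1e-6
KMEANS_MAX_ITER = 300


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PCAModel:
    loadings: np.ndarray  # variables x components eigenvectors (sign-fixed)
    eigenvalues: np.ndarray  # correlation-matrix eigenvalues, nonincreasing
    explained_fraction: np.ndarray  # eigenvalue / sum(eigenvalues)
    scores: np.ndarray  # subjects x components projections

    @property
    def n_components(self) -> int:
        return self.eigenvalues.size


def pca_project(z: np.ndarray) -> PCAModel:
    """Eigen-decomposition of the correlation structure of z-scored data.

    Components are sign-fixed so each one's largest-magnitude loading is
    positive, making the output deterministic.  Zero eigenvalues (rank
    deficiency) are truncated.
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite entries in PCA input")
    n = z.shape[0]
    u, s, vt = np.linalg.svd(z - z.mean(axis=0), full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    keep = eigenvalues > 1e-10 * max(eigenvalues.max(), 1.0)
    eigenvalues = eigenvalues[keep]
    loadings = vt[keep].T  # variables x components
    for j in range(loadings.shape[1]):
        if loadings[np.argmax(np.abs(loadings[:, j])), j] < 0:
            loadings[:, j] = -loadings[:, j]
    scores = (z - z.mean(axis=0)) @ loadings
    explained = eigenvalues / eigenvalues.sum()
    return PCAModel(loadings=loadings, eigenvalues=eigenvalues,
                    explained_fraction=explained, scores=scores)


def retain_components(model: PCAModel) -> int:
    """Kaiser-Guttman rule: number of eigenvalues > 1 (at least 1, with a
    warning when no eigenvalue exceeds 1)."""
    n = int(np.sum(model.eigenvalues > 1.0))
    if n == 0:
        warnings.warn("no eigenvalue exceeds 1; retaining the largest component")
        return 1
    return n


@dataclass(frozen=True)
class ImportanceVector:
    """Variance-weighted per-variable importance, signed and rectified.

    ABC categorization consumes the absolute version, since the row sums can
    be negative while ABC needs positive data.
    """

    signed: np.ndarray
    @property
    def absolute(self) -> np.ndarray:
        return np.abs(self.signed)


def pca_variable_importance(
    z: np.ndarray, model: PCAModel, n_retained: int | None = None
) -> ImportanceVector:
    """Importance of each variable for the retained component subspace.

    The variable x component association matrix (dot products of each
    z-scored variable with each component's score vector) is z-transformed
    within each component, weighted by that component's explained-variance
    fraction, and summed across the retained components; the magnitude of the
    row sum is the variable's importance.  Setting ``n_retained`` to the full
    component count gives the whole-space variant.
    """
    if n_retained is None:
        n_retained = retain_components(model)
    if n_retained > model.n_components:
        raise ValueError(
            f"n_retained={n_retained} exceeds available components ({model.n_components})"
        )
    assoc = np.asarray(z, dtype=float).T @ model.scores  # variables x components
    mu = assoc.mean(axis=0)
    sd = assoc.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    weighted = (assoc - mu) / sd * model.explained_fraction
    return ImportanceVector(signed=weighted[:, :n_retained].sum(axis=1))


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterSolution:
    k: int
    labels: np.ndarray
    centers: np.ndarray
    silhouettes: np.ndarray  # per subject, in [-1, 1]
    @property
    def mean_silhouette(self) -> float:
        return float(self.silhouettes.mean())


def _silhouettes(x: np.ndarray, labels: np.ndarray) -> np.ndarray:
    if np.unique(labels).size < 2:
        return np.zeros(len(labels))
    return silhouette_samples(x, labels, metric="euclidean")


def kmeans_cluster(scores: np.ndarray, k: int, seed: int = 0) -> ClusterSolution:
    """Lloyd's k-means (k-means++ init, 25 restarts, Euclidean silhouettes)."""
    x = np.asarray(scores, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k >= len(x):
        raise ValueError("k must be smaller than the number of subjects")
    km = KMeans(
        n_clusters=k, init="k-means++", n_init=KMEANS_RESTARTS,
        max_iter=KMEANS_MAX_ITER, tol=KMEANS_TOL, random_state=seed,
    ).fit(x)
    return ClusterSolution(
        k=k, labels=km.labels_.copy(), centers=km.cluster_centers_.copy(),
        silhouettes=_silhouettes(x, km.labels_),
    )


def select_k_by_silhouette(
    scores: np.ndarray, k_range=range(2, 6), seed: int = 0
) -> tuple[int, dict[int, ClusterSolution]]:
    """Fit each k and return the one maximizing mean silhouette (ties -> smaller k)."""
    solutions = {k: kmeans_cluster(scores, k, seed=seed) for k in k_range}
    best_k = min(solutions, key=lambda k: (-solutions[k].mean_silhouette, k))
    return best_k, solutions


@dataclass(frozen=True)
class StabilityReport:
    silhouette_per_run: np.ndarray
    ari_per_run: np.ndarray
    @property
    def mean_silhouette(self) -> float:
        return float(self.silhouette_per_run.mean())
    @property
    def mean_ari(self) -> float:
        return float(self.ari_per_run.mean())
    @property
    def n_runs(self) -> int:
        return self.silhouette_per_run.size


def bootstrap_stability(
    scores: np.ndarray,
    reference_labels: np.ndarray,
    n_runs: int = 20,
    seed: int = 0,
) -> StabilityReport:
    """Cluster-stability assessment by bootstrap resampling.

    Each run redraws n subjects with replacement, re-clusters at the
    reference k, and records (a) the run's mean silhouette and (b) the
    adjusted Rand index between the run's labels and the reference labels on
    the unique resampled subjects.  Degenerate single-cluster runs score
    ARI 0.
    """
    x = np.asarray(scores, dtype=float)
    reference_labels = np.asarray(reference_labels)
    k = int(np.unique(reference_labels).size)
    rng = np.random.default_rng(seed)
    sils, aris = np.empty(n_runs), np.empty(n_runs)
    for r in range(n_runs):
        idx = rng.integers(0, len(x), size=len(x))
        run_seed = int(rng.integers(0, 2**31 - 1))
        sol = kmeans_cluster(x[idx], k, seed=run_seed)
        sils[r] = sol.mean_silhouette
        uniq, first_pos = np.unique(idx, return_index=True)
        run_on_unique = sol.labels[first_pos]
        if np.unique(run_on_unique).size < 2:
            aris[r] = 0.0
        else:
            aris[r] = adjusted_rand_index(reference_labels[uniq], run_on_unique)
    return StabilityReport(silhouette_per_run=sils, ari_per_run=aris)


def _pam(x: np.ndarray, k: int, seed: int = 0, max_swaps: int = 200) -> np.ndarray:
    """Partitioning around medoids (BUILD + SWAP) on Euclidean distances."""
    d = cdist(x, x)
    n = len(x)
    # BUILD: greedy cost-minimizing medoid additions
    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < k:
        best_j, best_cost = None, np.inf
        current = d[:, medoids].min(axis=1)
        for j in range(n):
            if j in medoids:
                continue
            cost = np.minimum(current, d[:, j]).sum()
            if cost < best_cost:
                best_j, best_cost = j, cost
        medoids.append(best_j)
    # SWAP until no improvement
    for _ in range(max_swaps):
        cost = d[:, medoids].min(axis=1).sum()
        best = (None, None, cost)
        for mi, m in enumerate(medoids):
            others = [mm for mm in medoids if mm != m]
            partial = d[:, others].min(axis=1) if others else np.full(n, np.inf)
            for j in range(n):
                if j in medoids:
                    continue
                new_cost = np.minimum(partial, d[:, j]).sum()
                if new_cost < best[2] - 1e-12:
                    best = (mi, j, new_cost)
        if best[0] is None:
            break
        medoids[best[0]] = best[1]
    return np.argmin(d[:, medoids], axis=1)


def compare_clusterers(scores: np.ndarray, k: int, seed: int = 0) -> dict[str, float]:
    """Mean silhouette of k-means, Ward agglomeration, and PAM at the same k."""
    x = np.asarray(scores, dtype=float)
    out = {"kmeans": kmeans_cluster(x, k, seed=seed).mean_silhouette}
    ward = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(x)
    out["ward"] = float(_silhouettes(x, ward).mean())
    pam = _pam(x, k, seed=seed)
    out["pam"] = float(_silhouettes(x, pam).mean())
    return out


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Permutation-model adjusted Rand index from the contingency table."""
    a, b = np.asarray(labels_a), np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    n = a.size
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    contingency = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(contingency, (ai, bi), 1)

    def comb2(m):
        return m * (m - 1) / 2.0

    sum_cells = comb2(contingency).sum()
    sum_rows = comb2(contingency.sum(axis=1)).sum()
    sum_cols = comb2(contingency.sum(axis=0)).sum()
    expected = sum_rows * sum_cols / comb2(n)
    max_index = 0.5 * (sum_rows + sum_cols)
    if max_index == expected:  # both partitions trivial
        return 1.0
    return float((sum_cells - expected) / (max_index - expected))
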