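import warnings

import numpy as np
import pytest

import olfphen as op

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic cohort with its planted labels."""
    return op.generate_cohort(op.SyntheticConfig(seed=5))


@pytest.fixture(scope="session")
def preprocessed(cohort):
    """The same cohort after transform -> filter -> impute -> z-standardize.

    Returns (imputed_table, z_table, aligned_labels).  Imputation runs with a
    small forest; quality margins in the tests account for that.
    """
    table, labels = cohort
    table = op.transform_table(table)
    table = op.filter_missingness(table)
    labels = labels[np.asarray(table.subject_ids)]
    table = op.impute_chained_rf(table, seed=7, n_estimators=30, max_iter=2)
    z_table = op.z_standardize(table)
    return table, z_table, labels


def blobs(n_per=40, d=4, separation=10.0, k=2, seed=0):
    """Well-separated spherical Gaussian blobs for clustering sanity checks.

    Centers sit on orthogonal axes, so every pair is separation*sqrt(2) apart.
    """
    assert k <= d
    rng = np.random.default_rng(seed)
    centers = separation * np.eye(d)[:k]
    x = np.vstack([c + rng.normal(size=(n_per, d)) for c in centers])
    y = np.repeat(np.arange(k), n_per)
    return x, y
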