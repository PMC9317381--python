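"""Synthetic cohort generator.

The raw study data are available only on request, so the pipeline ships a
generator that emulates their statistical structure: n = 135 subjects in two
latent phenotype clusters of 80 and 55, fifteen olfaction variables plus
age/sex/BMI, a between-cluster effect-size profile concentrated in the four
dilution-sorting variables, within-block correlations (questionnaire items,
peanut-test distances, Sniffin' discrimination/identification), right-skewed
marginals for thresholds and distances, and ~4% of olfaction cells missing
completely at random.

Cluster signal is injected as mean shifts on a latent Gaussian with unit
variances, *before* the marginal transforms and the missingness mask, so a
configured shift of d latent standard deviations is the configured Cohen's d.

A second, behavioural-level generator draws dilution-sorting responses from a
Mallows permutation model (repeated-insertion sampling) so the footrule
scoring rules can be exercised end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import ROLE_COVARIATE, ROLE_OLFACTION, CohortTable, VariableMeta
from .scoring import N_SORT_ITEMS

#: The fifteen olfaction analysis variables, in battery order.
OLFACTION_VARIABLES = (
    "olfthresh",
    "olfdis",
    "olfident",
    "distance_right",
    "distance_left",
    "score_pea",
    "score_pea_time",
    "score_eug",
    "score_eug_time",
    "lateralization",
    "enantiomers",
    "threshold_after_adaptation",
    "importance_association",
    "importance_application",
    "importance_consequence",
)

COVARIATES = ("age", "sex", "bmi")

#: The four sorting-task variables carrying the planted cluster signal.
SORTING_VARIABLES = ("score_pea", "score_pea_time", "score_eug", "score_eug_time")

# Between-cluster shifts in latent SD units (cluster 1 minus cluster 0).
# Sorting errors are larger (worse) in cluster 1; olfactory performance
# measures are smaller; the shift magnitudes follow a large/medium/small
# profile: sorting ~1.0-1.3, importance-of-application 0.8, peanut distances
# 0.7, Sniffin' subtests 0.3-0.45, everything else at most 0.2.
DEFAULT_EFFECT_SIZES: dict[str, float] = {
    "olfthresh": -0.45,
    "olfdis": -0.40,
    "olfident": -0.30,
    "distance_right": -0.70,
    "distance_left": -0.70,
    "score_pea": 1.20,
    "score_pea_time": 1.30,
    "score_eug": 1.20,
    "score_eug_time": 1.00,
    "lateralization": -0.15,
    "enantiomers": -0.20,
    "threshold_after_adaptation": -0.20,
    "importance_association": -0.10,
    "importance_application": -0.80,
    "importance_consequence": -0.15,
}

#: Correlated variable blocks (within-block latent Pearson r).
DEFAULT_BLOCKS: dict[str, tuple[str, ...]] = {
    "questionnaire": (
        "importance_association",
        "importance_application",
        "importance_consequence",
    ),
    "peanut": ("distance_right", "distance_left"),
    "sniffin_no_threshold": ("olfdis", "olfident"),
}

#: Marginal families; unlisted variables are (affine) normal.
DEFAULT_MARGINAL_FAMILY: dict[str, str] = {
    "olfthresh": "lognormal",
    "distance_right": "lognormal",
    "distance_left": "lognormal",
    "threshold_after_adaptation": "lognormal",
}

# (location, scale) of each marginal: normal -> loc + scale * z,
# lognormal -> exp(loc + scale * z).  Chosen to land on plausible clinical
# ranges (thresholds ~ dilution steps, subtests ~ 0-16, distances in cm,
# sorting errors 0-12, errors/s ~ 0.05).
_MARGINAL_PARAMS: dict[str, tuple[float, float]] = {
    "olfthresh": (1.9, 0.40),
    "olfdis": (13.0, 2.0),
    "olfident": (13.5, 1.8),
    "distance_right": (1.8, 0.6),
    "distance_left": (1.8, 0.6),
    "score_pea": (4.0, 2.5),
    "score_pea_time": (0.055, 0.025),
    "score_eug": (4.5, 2.5),
    "score_eug_time": (0.050, 0.022),
    "lateralization": (30.0, 5.0),
    "enantiomers": (2.5, 0.8),
    "threshold_after_adaptation": (1.5, 0.5),
    "importance_association": (11.0, 3.0),
    "importance_application": (10.0, 3.0),
    "importance_consequence": (10.5, 3.0),
}

# Cluster-wise demographics: P(female), age mean/SD, BMI shift echoing the
# reported 56/80 vs 27/55 female split and 28 +/- 9.7 vs 34 +/- 13.2 years.
_P_FEMALE = (0.70, 0.49)
_AGE_PARAMS = ((28.0, 9.7), (34.0, 13.2))
# BMI ~ u**-2 with u normal: right-skewed, and the reciprocal square root
# (1/sqrt(BMI) = u) is exactly normal, emulating the transform its
# distribution calls for.  Centred near 23 kg/m2 with SD ~ 4.
_BMI_INV_ROOT = (0.2085, 0.018)
_BMI_SHIFT = 0.10  # latent-SD shift, cluster 1 slightly higher


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition parameters of the synthetic cohort."""

    n_subjects: int = 135
    cluster_sizes: tuple[int, ...] = (80, 55)
    effect_sizes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_SIZES)
    )
    block_correlation: float = 0.5
    blocks: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_BLOCKS)
    )
    missing_fraction: float = 0.04
    marginal_family: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_MARGINAL_FAMILY)
    )
    #: cluster-dependent demographics (female fraction, age, BMI shift); turn
    #: off together with zeroed effect_sizes for a fully null cohort
    demographic_shifts: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.cluster_sizes) != self.n_subjects:
            raise ValueError(
                f"cluster_sizes {self.cluster_sizes} must sum to n_subjects={self.n_subjects}"
            )
        if len(self.cluster_sizes) != 2:
            raise ValueError("the generator plants exactly two clusters")
        if not 0 <= self.missing_fraction < 0.2:
            raise ValueError(
                "missing_fraction must lie in [0, 0.2): the pipeline's retention "
                "rule drops variables with >= 20% missing"
            )
        if not -1 < self.block_correlation < 1:
            raise ValueError("block_correlation must lie in (-1, 1)")
        bad = [v for v, d in self.effect_sizes.items() if not math.isfinite(d)]
        if bad:
            raise ValueError(f"non-finite effect sizes for {bad}")
        unknown = set(self.effect_sizes) - set(OLFACTION_VARIABLES)
        if unknown:
            raise ValueError(f"effect sizes for unknown variables: {sorted(unknown)}")


def _latent_correlation(config: SyntheticConfig) -> np.ndarray:
    d = len(OLFACTION_VARIABLES)
    corr = np.eye(d)
    idx = {v: i for i, v in enumerate(OLFACTION_VARIABLES)}
    for members in config.blocks.values():
        for a in members:
            for b in members:
                if a != b:
                    corr[idx[a], idx[b]] = config.block_correlation
    return corr


def generate_cohort(config: SyntheticConfig | None = None) -> tuple[CohortTable, np.ndarray]:
    """Draw one synthetic cohort.

    Returns the cohort table (15 olfaction variables + age/sex/BMI, with the
    configured fraction of olfaction cells masked) and the true cluster
    labels (0/1).  Identical config (including seed) gives identical output.
    Missingness is confined to olfaction variables; covariates are complete.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    labels = np.repeat(np.arange(len(config.cluster_sizes)), config.cluster_sizes)

    corr = _latent_correlation(config)
    chol = np.linalg.cholesky(corr)
    latent = rng.standard_normal((n, len(OLFACTION_VARIABLES))) @ chol.T
    for j, var in enumerate(OLFACTION_VARIABLES):
        d = config.effect_sizes.get(var, 0.0)
        latent[:, j] += np.where(labels == 1, d / 2.0, -d / 2.0)

    data = {}
    for j, var in enumerate(OLFACTION_VARIABLES):
        loc, scale = _MARGINAL_PARAMS[var]
        z = latent[:, j]
        if config.marginal_family.get(var) == "lognormal":
            data[var] = np.exp(loc + scale * z)
        else:
            data[var] = loc + scale * z

    # covariates: complete by construction
    if config.demographic_shifts:
        age_params, p_female, bmi_shift = _AGE_PARAMS, _P_FEMALE, _BMI_SHIFT
    else:  # pooled cohort demographics, independent of cluster
        age_params, p_female, bmi_shift = ((30.5, 11.6),) * 2, (0.615,) * 2, 0.0
    age = np.empty(n)
    for g, (mu, sd) in enumerate(age_params):
        mask = labels == g
        age[mask] = mu + sd * rng.standard_normal(mask.sum())
    sex = (rng.random(n) < np.asarray(p_female)[labels]).astype(float)  # 1 = female
    bmi_z = rng.standard_normal(n) + np.where(labels == 1, bmi_shift, 0.0)
    bmi = (_BMI_INV_ROOT[0] - _BMI_INV_ROOT[1] * bmi_z) ** -2.0
    data["age"], data["sex"], data["bmi"] = age, sex, bmi

    values = pd.DataFrame(data, columns=list(OLFACTION_VARIABLES) + list(COVARIATES))
    values.index = pd.RangeIndex(n, name="subject_id")

    # MCAR mask on olfaction cells only, with an exact cell count
    n_cells = n * len(OLFACTION_VARIABLES)
    n_mask = int(round(config.missing_fraction * n_cells))
    if n_mask:
        flat = rng.choice(n_cells, size=n_mask, replace=False)
        rows, cols = np.unravel_index(flat, (n, len(OLFACTION_VARIABLES)))
        arr = values.to_numpy()
        arr[rows, cols] = np.nan
        values = pd.DataFrame(arr, columns=values.columns, index=values.index)

    meta = {v: VariableMeta(v, ROLE_OLFACTION) for v in OLFACTION_VARIABLES}
    meta.update({v: VariableMeta(v, ROLE_COVARIATE) for v in COVARIATES})
    return CohortTable(values, meta), labels


# ---------------------------------------------------------------------------
# behavioural-level sorting responses (Mallows model)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SortingSimConfig:
    """Mallows-type noise model for the dilution-sorting task.

    ``dispersion`` >= 0 controls how far responses stray from the correct
    ascending order (0 = every subject sorts perfectly); task durations are
    lognormal in seconds.
    """

    n_items: int = N_SORT_ITEMS
    dispersion: float = 0.5
    time_log_mean: float = math.log(60.0)
    time_log_sd: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_items != N_SORT_ITEMS:
            raise ValueError(f"the sorting task uses exactly {N_SORT_ITEMS} dilutions")
        if self.dispersion < 0:
            raise ValueError("dispersion must be nonnegative")
        if self.time_log_sd < 0:
            raise ValueError("time_log_sd must be nonnegative")


def _sample_mallows(rng: np.random.Generator, n_items: int, dispersion: float) -> tuple[int, ...]:
    """Repeated-insertion sampling from a Mallows model centred on identity.

    phi = 1 - exp(-dispersion) in [0, 1): item k is inserted j slots from the
    back of the current prefix with probability proportional to phi**j, which
    yields the Mallows distribution with Kendall-distance kernel.
    """
    phi = 1.0 - math.exp(-dispersion)
    order: list[int] = []
    for k in range(1, n_items + 1):
        if phi == 0.0:
            order.append(k)
            continue
        weights = phi ** np.arange(k, dtype=float)  # j = 0 .. k-1 slots from back
        weights /= weights.sum()
        j = rng.choice(k, p=weights)
        order.insert(len(order) - j, k)
    return tuple(order)


def generate_sorting_responses(
    n_per_cluster: tuple[int, ...],
    configs: tuple[SortingSimConfig, ...] | SortingSimConfig,
) -> list[tuple[tuple[int, ...], float]]:
    """Draw (permutation, duration-in-seconds) sorting responses.

    ``n_per_cluster`` gives the number of subjects per cluster; ``configs`` is
    one ``SortingSimConfig`` per cluster (or a single config for all).  With
    dispersion 0 every response is the identity permutation.
    """
    if isinstance(configs, SortingSimConfig):
        configs = tuple(configs for _ in n_per_cluster)
    if len(configs) != len(n_per_cluster):
        raise ValueError("need one SortingSimConfig per cluster")
    responses = []
    for n, cfg in zip(n_per_cluster, configs):
        rng = np.random.default_rng(cfg.seed)
        for _ in range(n):
            perm = _sample_mallows(rng, cfg.n_items, cfg.dispersion)
            duration = float(np.exp(cfg.time_log_mean + cfg.time_log_sd * rng.standard_normal()))
            responses.append((perm, duration))
    return responses
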