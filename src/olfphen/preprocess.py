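"""Distribution-aware preprocessing.

Each variable's distribution is examined with the D'Agostino-Pearson omnibus
normality test; the Tukey ladder-of-powers transform that makes the variable
most normal (largest test p-value) is selected and recorded.  Variables or
cases with >= 20% missing values are dropped; the remaining missing olfaction
cells are imputed by chained random-forest regression (MICE-style), and the
olfaction variables are finally z-standardized for projection and clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer

from .cohort import CohortTable

#: Canonical Tukey ladder grid; 0 stands for the logarithm.
TUKEY_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0)

MIN_SAMPLES_NORMALITY = 20  # the kurtosis z-score needs n >= 20


@dataclass(frozen=True)
class TukeyPower:
    """One rung of Tukey's ladder, with an offset making the data positive.

    Negative powers are applied as -(x ** p) so every rung is a monotonically
    increasing map on the (shifted) data.
    """

    power: float
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.power not in TUKEY_POWERS:
            raise ValueError(f"power must be one of {TUKEY_POWERS}")

    def apply(self, values: np.ndarray) -> np.ndarray:
        x = np.asarray(values, dtype=float) + self.offset
        finite = x[np.isfinite(x)]
        if self.power in (0.0, 0.5, -0.5, -1.0, -2.0) and np.any(finite <= 0):
            raise ValueError(
                f"power {self.power} needs positive data; offset {self.offset} insufficient"
            )
        if self.power == 0.0:
            return np.log(x)
        if self.power < 0:
            return -(x ** self.power)
        return x ** self.power

    def label(self) -> str:
        name = "log" if self.power == 0.0 else f"power:{self.power:g}"
        return name if self.offset == 0.0 else f"{name}+offset:{self.offset:g}"


def dagostino_pearson(values) -> tuple[float, float]:
    """D'Agostino-Pearson omnibus K2 statistic and p-value.

    K2 combines the skewness and kurtosis z-scores; p comes from chi-square
    with 2 df.  Requires >= 20 non-missing values and nonzero variance.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < MIN_SAMPLES_NORMALITY:
        raise ValueError(f"need >= {MIN_SAMPLES_NORMALITY} non-missing values, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("constant vector: normality test undefined")
    stat, p = stats.normaltest(x)
    return float(stat), float(p)


def _tie_break_key(power: float) -> tuple:
    # prefer no transform, then milder transforms, then positive powers
    return (power != 1.0, abs(power), power < 0)


def select_tukey_transform(values) -> tuple[TukeyPower, np.ndarray]:
    """Pick the ladder rung maximizing D'Agostino-Pearson normality p.

    Ties go to power 1 (identity), then to the smaller |power|.  Nonpositive
    data are shifted by 1 - min(x) before log/root/negative rungs.  Returns
    the chosen transform and the transformed values (NaNs preserved).
    """
    x = np.asarray(values, dtype=float)
    obs = x[np.isfinite(x)]
    if obs.size < MIN_SAMPLES_NORMALITY:
        raise ValueError(f"need >= {MIN_SAMPLES_NORMALITY} non-missing values")
    if np.ptp(obs) == 0:
        raise ValueError("constant input: no transform selectable")
    offset = 0.0 if obs.min() > 0 else float(1.0 - obs.min())

    best: tuple[TukeyPower, np.ndarray, float] | None = None
    for power in TUKEY_POWERS:
        tp = TukeyPower(power, offset if power != 1.0 else 0.0)
        try:
            transformed = tp.apply(x)
        except ValueError:
            continue
        obs_t = transformed[np.isfinite(transformed)]
        if obs_t.size < MIN_SAMPLES_NORMALITY or np.ptp(obs_t) == 0:
            continue
        _, p = dagostino_pearson(obs_t)
        if (
            best is None
            or p > best[2]
            or (p == best[2] and _tie_break_key(power) < _tie_break_key(best[0].power))
        ):
            best = (tp, transformed, p)
    assert best is not None  # power 1 always evaluates
    return best[0], best[1]


def transform_table(table: CohortTable, columns: list[str] | None = None) -> CohortTable:
    """Apply the selected Tukey transform to each listed column (default: the
    olfaction variables plus BMI), recording the choice in the metadata."""
    out = table.copy()
    if columns is None:
        columns = table.olfaction_columns + (["bmi"] if "bmi" in table.values.columns else [])
    for col in columns:
        tp, transformed = select_tukey_transform(out.values[col].to_numpy())
        if tp.power != 1.0:
            out.values[col] = transformed
        out.set_transform(col, tp.label() if tp.power != 1.0 else None)
    return out


def filter_missingness(table: CohortTable, cutoff: float = 0.20) -> CohortTable:
    """Retain only variables, then cases, with < ``cutoff`` missing values."""
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must lie in (0, 1]")
    frac_var = table.values.isna().mean(axis=0)
    keep_vars = [c for c in table.values.columns if frac_var[c] < cutoff]
    if not keep_vars:
        raise ValueError("all variables exceed the missingness cutoff")
    values = table.values[keep_vars]
    frac_case = values.isna().mean(axis=1)
    values = values.loc[frac_case < cutoff]
    return table.with_values(values.copy())


def impute_chained_rf(
    table: CohortTable,
    seed: int = 0,
    n_estimators: int = 100,
    max_iter: int = 5,
) -> CohortTable:
    """Chained random-forest (MICE-style) imputation of olfaction variables.

    Covariates may serve as predictors but are never imputed (and must be
    complete).  Observed cells are untouched; imputed values are clamped to
    the observed range of their variable; identical seeds give identical
    imputations.
    """
    frac = table.values.isna().mean(axis=0)
    too_missing = [c for c in table.values.columns if frac[c] >= 0.2]
    if too_missing:
        raise ValueError(f"variables exceed 20% missing (filter first): {too_missing}")
    empty = [c for c in table.values.columns if table.values[c].isna().all()]
    if empty:
        raise ValueError(f"variables with no observed values: {empty}")
    if not table.values.isna().to_numpy().any():
        return table.copy()

    cols = list(table.values.columns)
    x = table.values[cols].to_numpy(dtype=float)
    observed_min = np.nanmin(x, axis=0)
    observed_max = np.nanmax(x, axis=0)
    imputer = IterativeImputer(
        estimator=RandomForestRegressor(n_estimators=n_estimators, random_state=seed),
        max_iter=max_iter,
        random_state=seed,
        min_value=observed_min,
        max_value=observed_max,
        sample_posterior=False,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence chatter at max_iter
        filled = imputer.fit_transform(x)

    out = table.copy()
    filled_df = pd.DataFrame(filled, columns=cols, index=table.values.index)
    # only olfaction cells are imputed; covariates are complete by contract
    for col in table.olfaction_columns:
        out.values[col] = filled_df[col]
    return out


def z_standardize(table: CohortTable, columns: list[str] | None = None) -> CohortTable:
    """Center and scale the listed columns (default: olfaction) to mean 0,
    sample SD 1 (ddof=1)."""
    out = table.copy()
    for col in columns if columns is not None else table.olfaction_columns:
        x = out.values[col].to_numpy(dtype=float)
        if np.isnan(x).any():
            raise ValueError(f"column {col!r} still has missing values; impute first")
        sd = x.std(ddof=1)
        if sd == 0:
            raise ValueError(f"column {col!r} has zero variance")
        out.values[col] = (x - x.mean()) / sd
    return out
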