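"""Cohort feature table: a subjects x variables matrix with roles and transforms.

The table is the central container of the pipeline.  Values live in a pandas
DataFrame (NaN marks a missing cell); per-variable metadata records whether a
column is an olfaction variable (enters PCA/clustering/feature selection) or a
covariate (age, sex, BMI: used in group tests and supervised models only), and
which power transform, if any, has been applied to it.

On disk a cohort is a plain CSV (empty cells = missing) plus a YAML sidecar
mapping every column to its role and transform, so that runs stay auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

ROLE_OLFACTION = "olfaction"
ROLE_COVARIATE = "covariate"
_VALID_ROLES = (ROLE_OLFACTION, ROLE_COVARIATE)


@dataclass(frozen=True)
class VariableMeta:
    """Role and transform bookkeeping for one column."""

    name: str
    role: str = ROLE_OLFACTION
    transform: str | None = None  # e.g. "log", "power:0.5", "power:-0.5+offset:1.0"

    def __post_init__(self) -> None:
        if self.role not in _VALID_ROLES:
            raise ValueError(f"unknown role {self.role!r} for variable {self.name!r}")


@dataclass
class CohortTable:
    """Rectangular subjects x variables store with missingness awareness.

    ``values`` holds one row per subject; missing cells are NaN.  ``meta`` must
    cover every column.  The missingness mask is derived (``values.isna()``)
    rather than stored, so it can never go out of sync.
    """

    values: pd.DataFrame
    meta: dict[str, VariableMeta] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cols = list(self.values.columns)
        if len(set(cols)) != len(cols):
            raise ValueError("duplicate column names in cohort table")
        missing_meta = [c for c in cols if c not in self.meta]
        if missing_meta:
            raise ValueError(f"columns without role metadata: {missing_meta}")
        extra = [m for m in self.meta if m not in cols]
        if extra:
            raise ValueError(f"metadata for absent columns: {extra}")

    # -- views ------------------------------------------------------------
    @property
    def subject_ids(self) -> pd.Index:
        return self.values.index

    @property
    def n_subjects(self) -> int:
        return len(self.values)

    @property
    def olfaction_columns(self) -> list[str]:
        return [c for c in self.values.columns if self.meta[c].role == ROLE_OLFACTION]

    @property
    def covariate_columns(self) -> list[str]:
        return [c for c in self.values.columns if self.meta[c].role == ROLE_COVARIATE]

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def olfaction_matrix(self) -> pd.DataFrame:
        return self.values[self.olfaction_columns]

    def copy(self) -> "CohortTable":
        return CohortTable(self.values.copy(), dict(self.meta))

    def with_values(self, values: pd.DataFrame) -> "CohortTable":
        """New table sharing metadata (restricted to the new columns)."""
        meta = {c: self.meta[c] for c in values.columns}
        return CohortTable(values, meta)

    def set_transform(self, column: str, transform: str | None) -> None:
        self.meta[column] = replace(self.meta[column], transform=transform)

    # -- I/O ---------------------------------------------------------------
    def write_csv(self, csv_path: str | Path, sidecar_path: str | Path) -> None:
        csv_path, sidecar_path = Path(csv_path), Path(sidecar_path)
        # %.17g round-trips float64 exactly through text
        self.values.to_csv(csv_path, index_label="subject_id", float_format="%.17g")
        sidecar = {
            "columns": {
                name: {"role": m.role, "transform": m.transform}
                for name, m in self.meta.items()
            }
        }
        sidecar_path.write_text(yaml.safe_dump(sidecar, sort_keys=False))


def read_cohort_csv(csv_path: str | Path, sidecar_path: str | Path) -> CohortTable:
    """Load a cohort CSV and its YAML role sidecar.

    Round-trips ``CohortTable.write_csv`` exactly, including the missingness
    mask (empty CSV cells become NaN).
    """
    csv_path, sidecar_path = Path(csv_path), Path(sidecar_path)
    if not sidecar_path.exists():
        raise FileNotFoundError(f"variable-role sidecar not found: {sidecar_path}")
    values = pd.read_csv(csv_path, index_col="subject_id", float_precision="round_trip")
    for col in values.columns:
        if not np.issubdtype(values[col].dtype, np.number):
            raise ValueError(f"non-numeric cells in column {col!r}")
    values = values.astype(float)
    sidecar = yaml.safe_load(sidecar_path.read_text())
    if not isinstance(sidecar, dict) or "columns" not in sidecar:
        raise ValueError(f"sidecar {sidecar_path} lacks a 'columns' mapping")
    meta = {}
    for name, entry in sidecar["columns"].items():
        meta[name] = VariableMeta(
            name=name,
            role=entry.get("role", ROLE_OLFACTION),
            transform=entry.get("transform"),
        )
    unmapped = [c for c in values.columns if c not in meta]
    if unmapped:
        raise ValueError(f"sidecar {sidecar_path} does not map columns: {unmapped}")
    return CohortTable(values, meta)
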