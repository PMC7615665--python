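"""Cohort table container, CSV round-trips, and inclusion/exclusion rules."""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .schema import (
    COVARIATE_COLUMNS,
    FAMILY_COLUMN,
    VariableSchema,
    pair_sets,
)

__all__ = [
    "CohortTable",
    "load_cohort",
    "save_cohort",
    "apply_exclusions",
    "completers_filter",
    "pair_sets",
]


@dataclass
class CohortTable:
    """Individuals x 13 scored variables plus covariates for one cohort.

    ``values`` holds the scores in canonical column order with ``NaN`` for
    missing cells; ``covariates`` carries the per-block ages and sex.
    """

    values: pd.DataFrame
    covariates: pd.DataFrame
    schema: VariableSchema
    cohort_id: str
    family_id: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if tuple(self.values.columns) != self.schema.names:
            raise ValueError("values columns must follow the canonical order")
        if len(self.covariates) != len(self.values):
            raise ValueError("covariates and values must have equal row counts")
        if self.family_id is not None and len(self.family_id) != len(self.values):
            raise ValueError("family_id length mismatch")

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mask(self) -> pd.DataFrame:
        """Observed-cell indicator (True = observed)."""
        return self.values.notna()

    def observed_trait_counts(self) -> pd.Series:
        return self.values[list(self.schema.trait_names)].notna().sum(axis=1)

    def take(self, keep: np.ndarray) -> "CohortTable":
        """Row subset preserving alignment of values/covariates/family ids."""
        fam = self.family_id.iloc[keep].reset_index(drop=True) if self.family_id is not None else None
        return replace(
            self,
            values=self.values.iloc[keep].reset_index(drop=True),
            covariates=self.covariates.iloc[keep].reset_index(drop=True),
            family_id=fam,
        )


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def save_cohort(table: CohortTable, path) -> None:
    """Write one header row and one row per individual; empty cell = missing."""
    out = pd.concat([table.values, table.covariates], axis=1)
    if table.family_id is not None:
        out[FAMILY_COLUMN] = table.family_id
    out.to_csv(path, sep=_sep_for(path), index=False, na_rep="")


def load_cohort(path, schema: VariableSchema) -> CohortTable:
    """Load a cohort CSV/TSV, validate against the schema, canonicalize order.

    Raises on unknown columns (listing the expected names) and on values
    outside the schema's scale bounds (reporting the offending row).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    expected = set(schema.names) | set(COVARIATE_COLUMNS) | {FAMILY_COLUMN}
    unknown = [c for c in df.columns if c not in expected]
    if unknown:
        raise ValueError(
            f"unknown column(s) {unknown}; expected a subset of {sorted(expected)}"
        )
    missing_vars = [c for c in schema.names if c not in df.columns]
    if missing_vars:
        raise ValueError(f"missing scored variable column(s): {missing_vars}")

    values = df[list(schema.names)].astype(float)
    for name, (lo, hi) in schema.bounds().items():
        col = values[name]
        bad = col.notna() & ((col < lo) | (col > hi))
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"column {name!r} value {col.iloc[row]} outside bounds "
                f"[{lo}, {hi}] at row {row}"
            )

    cov_cols = [c for c in COVARIATE_COLUMNS if c in df.columns]
    covariates = df[cov_cols].astype(float) if cov_cols else pd.DataFrame(index=df.index)
    family = df[FAMILY_COLUMN] if FAMILY_COLUMN in df.columns else None
    return CohortTable(
        values=values,
        covariates=covariates,
        schema=schema,
        cohort_id=schema.cohort_id,
        family_id=family,
    )


def apply_exclusions(
    table: CohortTable, one_per_family: bool = False, seed: int = 0
) -> CohortTable:
    """Drop rows with every trait missing; optionally keep one member per family.

    Family members are selected uniformly at random with the given seed, so
    repeated calls with the same seed retain the same individuals.
    """
    keep = table.observed_trait_counts().to_numpy() > 0
    out = table.take(np.flatnonzero(keep))
    if one_per_family and out.family_id is not None:
        rng = np.random.default_rng(seed)
        chosen: list[int] = []
        for _, idx in out.family_id.groupby(out.family_id).groups.items():
            idx = np.asarray(idx)
            chosen.append(int(rng.choice(idx)))
        out = out.take(np.sort(np.asarray(chosen)))
    return out


def completers_filter(table: CohortTable, min_frac: float) -> CohortTable:
    """Retain rows whose observed-trait fraction is at least ``min_frac``."""
    if not 0 < min_frac <= 1:
        raise ValueError("min_frac must be in (0, 1]")
    n_traits = len(table.schema.trait_names)
    frac = table.observed_trait_counts().to_numpy() / n_traits
    return table.take(np.flatnonzero(frac >= min_frac))
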