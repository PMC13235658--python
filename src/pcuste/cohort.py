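"""Cohort container and column-role schema.

A cohort is a plain :class:`pandas.DataFrame` — one row per participant —
paired with a :class:`CohortSchema` that names which columns play which role:
a binary outcome (1 = incident case, 0 = control), binary matching covariates
(sex, smoking, drinking, marital status, employment, education, income band),
and continuous predictors (age, anthropometrics, clinical biomarkers,
energy-adjusted nutrient intakes).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["CohortSchema", "CohortTable"]


@dataclass(frozen=True)
class CohortSchema:
    """Column roles for a cohort table.

    Parameters
    ----------
    outcome:
        Name of the binary outcome column (1 = case, 0 = control).
    covariates:
        Binary 0/1 indicator columns usable as matching covariates.
    predictors:
        Continuous predictor columns.
    participant_id:
        Opaque row identifier column.
    """

    outcome: str = "outcome"
    covariates: tuple[str, ...] = ()
    predictors: tuple[str, ...] = ()
    participant_id: str = "participant_id"

    def all_columns(self) -> list[str]:
        return [self.participant_id, self.outcome, *self.covariates, *self.predictors]


@dataclass
class CohortTable:
    """A participant table plus its schema.

    Invariants (checked by :meth:`validate`): the outcome is 0/1 for every
    row, covariates are 0/1, predictors are numeric with no missing values,
    and column names are unique.
    """

    data: pd.DataFrame
    schema: CohortSchema = field(default_factory=CohortSchema)

    def __post_init__(self) -> None:
        if self.schema.participant_id not in self.data.columns:
            self.data = self.data.copy()
            self.data.insert(0, self.schema.participant_id, np.arange(len(self.data)))

    # -- accessors -----------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def y(self) -> np.ndarray:
        return self.data[self.schema.outcome].to_numpy(dtype=int)

    @property
    def ids(self) -> np.ndarray:
        return self.data[self.schema.participant_id].to_numpy()

    @property
    def X(self) -> np.ndarray:
        """Predictor matrix (rows x continuous predictors)."""
        return self.data[list(self.schema.predictors)].to_numpy(dtype=float)

    @property
    def n_cases(self) -> int:
        return int(self.y.sum())

    @property
    def n_controls(self) -> int:
        return self.n - self.n_cases

    @property
    def prior(self) -> float:
        """Empirical case proportion (class prior)."""
        if self.n == 0:
            raise ValueError("empty cohort has no class prior")
        return self.n_cases / self.n

    def cases(self) -> "CohortTable":
        return self.subset(self.y == 1)

    def controls(self) -> "CohortTable":
        return self.subset(self.y == 0)

    def subset(self, mask) -> "CohortTable":
        return CohortTable(self.data.loc[mask].reset_index(drop=True), self.schema)

    def with_data(self, data: pd.DataFrame) -> "CohortTable":
        return CohortTable(data.reset_index(drop=True), self.schema)

    def with_predictors(self, predictors: tuple[str, ...]) -> "CohortTable":
        return CohortTable(self.data, replace(self.schema, predictors=tuple(predictors)))

    # -- validation ----------------------------------------------------
    def validate(self) -> "CohortTable":
        cols = list(self.data.columns)
        if len(cols) != len(set(cols)):
            raise ValueError("duplicate column names in cohort table")
        missing = [c for c in self.schema.all_columns() if c not in cols]
        if missing:
            raise ValueError(f"schema columns absent from table: {missing}")
        y = self.data[self.schema.outcome]
        if not y.isin([0, 1]).all():
            raise ValueError("outcome column must be binary 0/1")
        for c in self.schema.covariates:
            if not self.data[c].isin([0, 1]).all():
                raise ValueError(f"covariate {c!r} must be binary 0/1")
        pred = self.data[list(self.schema.predictors)]
        if pred.isna().any().any():
            bad = pred.columns[pred.isna().any()].tolist()
            raise ValueError(f"missing values in predictors: {bad}")
        return self
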