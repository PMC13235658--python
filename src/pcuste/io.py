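"""Delimited-text cohort I/O with a YAML/JSON column-role schema."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .cohort import CohortSchema, CohortTable

__all__ = ["read_schema", "read_cohort", "write_cohort", "write_json"]


def read_schema(path: str | Path) -> CohortSchema:
    """Read a column-role schema from YAML or JSON.

    Expected keys: ``outcome`` (str), ``covariates`` (list), ``predictors``
    (list), optional ``participant_id``.
    """
    text = Path(path).read_text()
    raw = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return CohortSchema(
        outcome=raw["outcome"],
        covariates=tuple(raw.get("covariates", ())),
        predictors=tuple(raw.get("predictors", ())),
        participant_id=raw.get("participant_id", "participant_id"),
    )


def read_cohort(path: str | Path, schema: CohortSchema, sep: str | None = None) -> CohortTable:
    sep = sep or ("\t" if str(path).endswith((".tsv", ".txt")) else ",")
    return CohortTable(pd.read_csv(path, sep=sep), schema).validate()


def write_cohort(table: CohortTable, path: str | Path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    table.data.to_csv(path, sep=sep, index=False)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=str) + "\n")
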