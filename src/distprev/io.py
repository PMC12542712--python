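"""Tabular I/O: person tables, crosswalks and estimate tables as CSV."""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd

from .crosswalk import XWALK_COLUMNS
from .synthetic import PERSON_COLUMNS

REQUIRED_PERSON_COLUMNS = ["person_id", "wave", "state_id", "district_id",
                           "cluster_id", "age", "sex", "weight"]


class SchemaError(ValueError):
    """A table is missing required columns."""


def _check_schema(df: pd.DataFrame, required: list[str], label: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{label}: missing required columns {missing}")


def read_survey_table(path: str | Path) -> pd.DataFrame:
    """Read a person-level table; extra columns are kept with a warning."""
    df = pd.read_csv(path)
    _check_schema(df, REQUIRED_PERSON_COLUMNS, str(path))
    known = set(PERSON_COLUMNS)
    extra = [c for c in df.columns if c not in known]
    if extra:
        warnings.warn(f"{path}: unknown extra columns {extra} retained",
                      stacklevel=2)
    return df


def write_survey_table(path: str | Path, persons: pd.DataFrame) -> None:
    _check_schema(persons, REQUIRED_PERSON_COLUMNS, str(path))
    persons.to_csv(path, index=False, float_format="%.10g")


def read_crosswalk(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_schema(df, XWALK_COLUMNS, str(path))
    return df


def write_crosswalk(path: str | Path, xwalk: pd.DataFrame) -> None:
    _check_schema(xwalk, XWALK_COLUMNS, str(path))
    xwalk.to_csv(path, index=False)


def write_estimates(path: str | Path, table: pd.DataFrame) -> None:
    """Write an estimate/change table; round-trips to full float precision."""
    table.to_csv(path, index=False, float_format="%.17g")


def read_estimates(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
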