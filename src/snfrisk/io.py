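"""Readers and writers shared by all pipeline stages.

Claims and facility tables travel as comma-separated text with a header
row (UTF-8); model objects are serialized to JSON by their own classes.
Reading validates the documented column contract and reports schema
violations with the column name and the first offending row.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "read_claims",
    "write_claims",
    "read_facilities",
    "write_facilities",
    "read_table",
    "write_table",
]

CLAIM_KEY_COLUMNS = ("claim_id", "patient_id", "state_id", "snf_id")
CLAIM_OUTCOME_COLUMNS = ("rehosp60", "death60")
CLAIM_CONTROL_COLUMNS = ("age", "female", "race", "complication", "los")


class SchemaError(ValueError):
    """A table violates the documented column contract."""


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required columns: {missing}")


def _check_binary(df: pd.DataFrame, columns, what: str) -> None:
    for col in columns:
        vals = df[col].to_numpy()
        bad = ~np.isin(vals, (0, 1))
        if bad.any():
            row = int(np.argmax(bad))
            raise SchemaError(
                f"{what} column {col!r} must be binary; first offending row "
                f"{row} has value {vals[row]!r}")


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_claims(claims: pd.DataFrame, path) -> None:
    _require_columns(claims, CLAIM_KEY_COLUMNS + CLAIM_OUTCOME_COLUMNS, "claim table")
    write_table(claims, path)


def read_claims(path) -> pd.DataFrame:
    """Read and validate a claim table (one row per SNF discharge)."""
    df = pd.read_csv(path)
    _require_columns(df, CLAIM_KEY_COLUMNS + CLAIM_OUTCOME_COLUMNS, "claim table")
    indicator_cols = [c for c in df.columns if c.startswith("ind_")]
    _check_binary(df, indicator_cols, "claim table")
    _check_binary(df, CLAIM_OUTCOME_COLUMNS, "claim table")
    if "excluded" in df.columns:
        _check_binary(df, ["excluded"], "claim table")
    # Every patient must map to exactly one state.
    n_states = df.groupby("patient_id")["state_id"].nunique()
    multi = n_states[n_states > 1]
    if len(multi):
        raise SchemaError(
            f"patients mapped to multiple states: {list(multi.index[:5])}")
    return df


def write_facilities(fac: pd.DataFrame, path) -> None:
    _require_columns(fac, ("snf_id",), "facility table")
    write_table(fac, path)


def read_facilities(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ("snf_id",), "facility table")
    if df["snf_id"].duplicated().any():
        dup = df.loc[df["snf_id"].duplicated(), "snf_id"].iloc[0]
        raise SchemaError(f"duplicated snf_id {dup!r} in facility table")
    return df
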