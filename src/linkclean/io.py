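"""CSV input/output for the source tables.

All tables travel as delimited text with a header row and ISO-8601 dates.
Missing values are empty fields; integer items that admit missingness
(parity, gestational age, birthweight, years/months of birth) use pandas
nullable ``Int64`` so that a missing parity is distinct from parity 0.
"""

from __future__ import annotations

import os

import pandas as pd

from .model import (CLAIM_COLUMNS, CONGENITAL_COLUMNS, DEATH_COLUMNS,
                    ENCOUNTER_COLUMNS, MAPPING_COLUMNS, PERINATAL_COLUMNS)

TABLE_COLUMNS = {
    "perinatal": PERINATAL_COLUMNS,
    "encounters": ENCOUNTER_COLUMNS,
    "deaths": DEATH_COLUMNS,
    "congenital": CONGENITAL_COLUMNS,
    "claims": CLAIM_COLUMNS,
    "mapping": MAPPING_COLUMNS,
}

_DATE_COLUMNS = {
    "perinatal": ["baby_dob"],
    "encounters": ["admission_date", "separation_date", "patient_dob"],
    "deaths": ["date_of_death"],
    "congenital": ["baby_dob"],
    "claims": ["date_of_supply"],
    "mapping": [],
}

_INT_COLUMNS = {
    "perinatal": ["gestational_age", "birthweight", "parity", "plurality",
                  "birth_order", "mother_yob", "mother_age", "apgar5"],
    "encounters": ["patient_yob", "patient_age", "month_of_birth", "is_delivery"],
    "deaths": [],
    "congenital": ["birthweight"],
    "claims": ["month_of_birth", "year_of_birth"],
    "mapping": [],
}

_FLOAT_COLUMNS = {"mapping": ["weight"]}


class SchemaError(ValueError):
    """A table does not conform to its declared schema."""


def coerce_table(df: pd.DataFrame, kind: str) -> pd.DataFrame:
    """Coerce dtypes and validate the schema of an in-memory table."""
    cols = TABLE_COLUMNS[kind]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{kind}: missing columns {missing}")
    out = df.loc[:, cols].copy()
    for c in _DATE_COLUMNS[kind]:
        out[c] = pd.to_datetime(out[c], format="ISO8601", errors="raise")
    for c in _INT_COLUMNS[kind]:
        out[c] = pd.to_numeric(out[c], errors="raise").astype("Int64")
    for c in _FLOAT_COLUMNS.get(kind, []):
        out[c] = pd.to_numeric(out[c], errors="raise").astype(float)
    id_col = "claim_id" if kind == "claims" else (
        None if kind == "mapping" else "record_id")
    if id_col is not None:
        out[id_col] = out[id_col].astype(str)
        if out[id_col].duplicated().any():
            dupes = out.loc[out[id_col].duplicated(), id_col].head().tolist()
            raise SchemaError(f"{kind}: non-unique {id_col}, e.g. {dupes}")
    if kind == "mapping" and out.duplicated(["patid", "mum_ppn"]).any():
        raise SchemaError("mapping: duplicated (patid, mum_ppn) pairs")
    return out.reset_index(drop=True)


def read_table(path: str | os.PathLike, kind: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = df.replace({"": None})
    return coerce_table(df, kind)


def write_table(df: pd.DataFrame, path: str | os.PathLike, kind: str) -> None:
    out = df.loc[:, TABLE_COLUMNS[kind]].copy()
    for c in _DATE_COLUMNS[kind]:
        out[c] = pd.to_datetime(out[c]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_tables(directory: str | os.PathLike) -> dict[str, pd.DataFrame]:
    """Read every recognised table CSV present in *directory*."""
    tables = {}
    for kind in TABLE_COLUMNS:
        path = os.path.join(directory, f"{kind}.csv")
        if os.path.exists(path):
            tables[kind] = read_table(path, kind)
    return tables


def write_tables(tables: dict[str, pd.DataFrame], directory: str | os.PathLike) -> None:
    os.makedirs(directory, exist_ok=True)
    for kind, df in tables.items():
        if kind in TABLE_COLUMNS:
            write_table(df, os.path.join(directory, f"{kind}.csv"), kind)
        else:
            df.to_csv(os.path.join(directory, f"{kind}.csv"), index=False)
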