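"""Readers and writers for the published dataset files.

Five tabular products make up the public database:

* ``indices.csv`` — species, euring_code, year, index, se
* ``trends.csv`` — species, euring_code, base_year, trend, se, class, note
* ``trends_short.csv`` — as trends.csv without the note column
* ``monitoring_schemes.csv`` — one row per national scheme (country,
  collaborators, scheme_name, count_method, plot_selection, initial_year,
  end_year, region, reference); a one-way converter to/from the spreadsheet
  form is provided
* ``species_country.csv`` — boolean matrix, rows species, columns country

All files are UTF-8 CSV with a mandatory header row; missing values are
empty fields.  Readers validate types and value ranges and reject bad rows
with a row-numbered error instead of coercing silently; write→read is an
identity on valid records.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .trends import CLASS_LABELS

__all__ = [
    "SchemaError",
    "read_indices",
    "write_indices",
    "read_trends",
    "write_trends",
    "read_trends_short",
    "write_trends_short",
    "read_schemes",
    "write_schemes",
    "schemes_to_xlsx",
    "read_species_country",
    "write_species_country",
]

INDICES_COLUMNS = ["species", "euring_code", "year", "index", "se"]
TRENDS_COLUMNS = ["species", "euring_code", "base_year", "trend", "se", "class", "note"]
TRENDS_SHORT_COLUMNS = TRENDS_COLUMNS[:-1]
SCHEMES_COLUMNS = [
    "country",
    "collaborators",
    "scheme_name",
    "count_method",
    "plot_selection",
    "initial_year",
    "end_year",
    "region",
    "reference",
]


class SchemaError(ValueError):
    """A file violates its published schema; message carries the row number."""


def _require_columns(df: pd.DataFrame, columns: list[str], path) -> None:
    if list(df.columns) != columns:
        raise SchemaError(
            f"{path}: header {list(df.columns)} does not match schema {columns}"
        )


def _check_rows(df: pd.DataFrame, path, checks) -> None:
    """Run (column, predicate, message) checks; report the first failing row.

    Row numbers are 1-based data rows (header excluded), matching what a
    person sees in a spreadsheet minus the header.
    """
    for col, ok, message in checks:
        bad = ~df[col].map(ok)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise SchemaError(f"{path}: row {row}: {message} (got {df[col].iloc[row - 1]!r})")


def _is_int(x) -> bool:
    try:
        return float(x) == int(float(x))
    except (TypeError, ValueError):
        return False


def _is_number(x) -> bool:
    try:
        return np.isfinite(float(x))
    except (TypeError, ValueError):
        return False


# -- indices ----------------------------------------------------------------


def read_indices(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"species": str}, float_precision="round_trip")
    _require_columns(df, INDICES_COLUMNS, path)
    _check_rows(
        df,
        path,
        [
            ("euring_code", _is_int, "euring_code must be an integer"),
            ("year", _is_int, "year must be an integer"),
            ("index", lambda x: _is_number(x) and float(x) > 0, "index must be positive"),
            ("se", lambda x: _is_number(x) and float(x) >= 0, "se must be non-negative"),
        ],
    )
    return df.astype({"euring_code": int, "year": int, "index": float, "se": float})


def write_indices(records: pd.DataFrame, path) -> None:
    _require_columns(records[INDICES_COLUMNS], INDICES_COLUMNS, path)
    records[INDICES_COLUMNS].to_csv(path, index=False)


# -- trends -----------------------------------------------------------------


def _read_trends_like(path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={"species": str, "note": str},
        keep_default_na=False,
        float_precision="round_trip",
    )
    # empty note fields are legitimate; other columns must not be empty
    _require_columns(df, columns, path)
    _check_rows(
        df,
        path,
        [
            ("euring_code", _is_int, "euring_code must be an integer"),
            ("base_year", _is_int, "base_year must be an integer"),
            ("trend", lambda x: _is_number(x) and float(x) > 0, "trend must be positive"),
            ("se", lambda x: _is_number(x) and float(x) >= 0, "se must be non-negative"),
            ("class", lambda x: x in CLASS_LABELS, "class must be one of the six labels"),
        ],
    )
    return df.astype(
        {"euring_code": int, "base_year": int, "trend": float, "se": float}
    )


def read_trends(path) -> pd.DataFrame:
    return _read_trends_like(path, TRENDS_COLUMNS)


def write_trends(records: pd.DataFrame, path) -> None:
    _require_columns(records[TRENDS_COLUMNS], TRENDS_COLUMNS, path)
    records[TRENDS_COLUMNS].to_csv(path, index=False)


def read_trends_short(path) -> pd.DataFrame:
    return _read_trends_like(path, TRENDS_SHORT_COLUMNS)


def write_trends_short(records: pd.DataFrame, path) -> None:
    frame = records[TRENDS_SHORT_COLUMNS]
    frame.to_csv(path, index=False)


# -- scheme metadata --------------------------------------------------------


def read_schemes(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False)
    _require_columns(df, SCHEMES_COLUMNS, path)
    _check_rows(
        df,
        path,
        [
            ("initial_year", _is_int, "initial_year must be an integer"),
            ("end_year", _is_int, "end_year must be an integer"),
            ("collaborators", _is_int, "collaborators must be an integer"),
        ],
    )
    df = df.astype({"initial_year": int, "end_year": int, "collaborators": int})
    bad = df["end_year"] < df["initial_year"]
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise SchemaError(f"{path}: row {row}: end_year precedes initial_year")
    return df


def write_schemes(records: pd.DataFrame, path) -> None:
    records[SCHEMES_COLUMNS].to_csv(path, index=False)


def schemes_to_xlsx(csv_path, xlsx_path) -> None:
    """One-way convenience conversion of the scheme list to spreadsheet form."""
    read_schemes(csv_path).to_excel(xlsx_path, index=False)


# -- species-by-country matrix ----------------------------------------------


def read_species_country(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    values = df.to_numpy()
    valid = np.isin(values, (0, 1, True, False))
    if not valid.all():
        i, j = np.argwhere(~valid)[0]
        raise SchemaError(
            f"{path}: row {i + 1}: entry for country {df.columns[j]!r} is not boolean"
        )
    return df.astype(bool)


def write_species_country(matrix: pd.DataFrame, path) -> None:
    matrix.astype(int).to_csv(path)
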