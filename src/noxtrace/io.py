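"""Delimited-text readers and writers with strict schema validation.

All tables are tab-separated text with a header row.  Readers validate the
header and report malformed rows by line number; writers always emit the
canonical header so that write -> read is an identity.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .synthetic import AMBIENT_COLUMNS, OBSERVATION_COLUMNS

__all__ = [
    "SchemaError",
    "read_observations",
    "write_observations",
    "read_ambient_records",
    "write_ambient_records",
    "read_config",
]

SEP = "\t"


class SchemaError(ValueError):
    """A table does not conform to its expected schema."""


def _read_table(
    path: str | Path,
    columns: tuple[str, ...],
    numeric: tuple[str, ...],
    integer: tuple[str, ...] = (),
) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=SEP, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    bad_lines: list[int] = []
    for col in numeric:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad_lines.extend(df.index[converted.isna()] + 2)  # +2: header, 1-based
        df[col] = converted
    if bad_lines:
        lines = ", ".join(str(i) for i in sorted(set(bad_lines)))
        raise SchemaError(f"{path}: non-numeric values on line(s) {lines}")
    for col in integer:
        df[col] = df[col].astype(int)
    return df[list(columns)]


def read_observations(path: str | Path) -> pd.DataFrame:
    """Read a replicate-level observation table.

    Expected columns: site_id, region, site_class, year, delta15n_permil.
    Malformed rows abort the read with their line numbers.
    """
    return _read_table(
        path,
        OBSERVATION_COLUMNS,
        numeric=("year", "delta15n_permil"),
        integer=("year",),
    )


def write_observations(observations: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in OBSERVATION_COLUMNS if c not in observations.columns]
    if missing:
        raise SchemaError(f"observation table is missing columns {missing}")
    observations[list(OBSERVATION_COLUMNS)].to_csv(path, sep=SEP, index=False)


def read_ambient_records(path: str | Path) -> pd.DataFrame:
    """Read an ambient-chemistry table (optionally with a d15n_wno3 column)."""
    df = pd.read_csv(path, sep=SEP, dtype=str, keep_default_na=False)
    columns = list(AMBIENT_COLUMNS)
    if "d15n_wno3" in df.columns:
        columns.append("d15n_wno3")
    missing = [c for c in AMBIENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    for col in columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        if converted.isna().any():
            lines = ", ".join(str(i + 2) for i in df.index[converted.isna()])
            raise SchemaError(f"{path}: non-numeric values on line(s) {lines}")
        df[col] = converted
    return df[columns]


def write_ambient_records(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, sep=SEP, index=False)


def read_config(path: str | Path) -> dict:
    """Load a YAML pipeline configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: configuration must be a mapping")
    return cfg
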