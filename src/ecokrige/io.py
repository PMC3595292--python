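"""CSV readers/writers for the point-table and time-series formats.

All tables are comma-separated with a header row, decimal points, and
ISO-8601 dates.  Readers validate row-by-row: under the default permissive
mode, rows failing validation are collected into an error report and the
remaining rows are returned; ``strict=True`` raises instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .density import TreeTable
from .errors import InvalidInputError
from .kriging import ObservationSet

logger = logging.getLogger(__name__)

__all__ = [
    "ReadReport",
    "read_observations",
    "write_observations",
    "read_trees",
    "write_trees",
    "read_timeseries",
    "write_timeseries",
    "read_point_table",
]

_SCHEMAS: dict[str, dict] = {
    "observations": {"required": ["site_id", "x", "y", "value"], "numeric": ["x", "y", "value"]},
    "trees": {"required": ["tree_id", "species", "x", "y", "habit"], "numeric": ["x", "y"]},
    "timeseries": {"required": ["date", "value"], "numeric": ["value"]},
}


@dataclass
class ReadReport:
    """Row-level validation outcome of one file read."""

    n_read: int
    n_valid: int
    errors: pd.DataFrame  # columns: row, reason
    n_merged_duplicates: int = 0

    @property
    def ok(self) -> bool:
        return self.errors.empty


def _read_table(path: str | Path, schema: str, strict: bool) -> tuple[pd.DataFrame, ReadReport]:
    spec = _SCHEMAS[schema]
    df = pd.read_csv(path)
    missing = [c for c in spec["required"] if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{path}: missing mandatory column(s) {missing}")
    n_read = len(df)
    bad: list[tuple[int, str]] = []
    for col in spec["numeric"]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        # empty cells are legitimate masked entries; non-numeric text is not
        invalid = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        for i in df.index[invalid]:
            bad.append((int(i), f"unparseable numeric in column {col!r}"))
        df[col] = coerced
    if schema == "timeseries":
        dates = pd.to_datetime(df["date"], errors="coerce", format="ISO8601")
        for i in df.index[dates.isna()]:
            bad.append((int(i), "unparseable ISO-8601 date"))
        df["date"] = dates
    bad_rows = sorted({r for r, _ in bad})
    if bad and strict:
        raise InvalidInputError(f"{path}: {len(bad_rows)} invalid row(s): {bad[:3]}...")
    if bad:
        logger.warning("%s: dropping %d invalid row(s)", path, len(bad_rows))
        df = df.drop(index=bad_rows).reset_index(drop=True)
    report = ReadReport(
        n_read=n_read,
        n_valid=len(df),
        errors=pd.DataFrame(bad, columns=["row", "reason"]),
    )
    return df, report


def read_observations(
    path: str | Path, date: str | None = None, strict: bool = False
) -> tuple[ObservationSet, ReadReport]:
    """Read a site-observation CSV (site_id, x, y, value).

    Rows with an empty value cell are treated as masked and dropped; exact
    duplicate coordinates are merged by mean with a logged warning (counted
    in the report).
    """
    df, report = _read_table(path, "observations", strict)
    df = df.dropna(subset=["x", "y", "value"])
    if df.empty:
        raise InvalidInputError(f"{path}: no valid observations")
    obs = ObservationSet.from_dataframe(df, date=date)
    report.n_merged_duplicates = len(df) - obs.n
    report.n_valid = obs.n
    return obs, report


def write_observations(obs: ObservationSet, path: str | Path) -> Path:
    path = Path(path)
    obs.to_dataframe().to_csv(path, index=False)
    return path


def read_trees(path: str | Path, strict: bool = False) -> tuple[TreeTable, ReadReport]:
    df, report = _read_table(path, "trees", strict)
    df = df.dropna(subset=["x", "y"]).reset_index(drop=True)
    return TreeTable(df), report


def write_trees(trees: TreeTable, path: str | Path) -> Path:
    path = Path(path)
    trees.table.to_csv(path, index=False)
    return path


def read_timeseries(path: str | Path, strict: bool = False) -> tuple[pd.Series, ReadReport]:
    """Read a (date, value) CSV into a date-indexed Series; empty value
    cells become NaN (masked) entries."""
    df, report = _read_table(path, "timeseries", strict)
    df = df.dropna(subset=["date"]).sort_values("date")
    if df["date"].duplicated().any():
        raise InvalidInputError(f"{path}: duplicated dates")
    series = pd.Series(df["value"].to_numpy(float), index=pd.DatetimeIndex(df["date"]))
    return series, report


def write_timeseries(series: pd.Series, path: str | Path) -> Path:
    path = Path(path)
    out = pd.DataFrame({"date": series.index.strftime("%Y-%m-%d"), "value": series.to_numpy()})
    out.to_csv(path, index=False)
    return path


def read_point_table(path: str | Path, schema: str, strict: bool = False):
    """Schema-dispatched reader: 'observations', 'trees' or 'timeseries'."""
    if schema not in _SCHEMAS:
        raise InvalidInputError(f"unknown schema {schema!r}; expected one of {sorted(_SCHEMAS)}")
    if schema == "observations":
        return read_observations(path, strict=strict)
    if schema == "trees":
        return read_trees(path, strict=strict)
    return read_timeseries(path, strict=strict)
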