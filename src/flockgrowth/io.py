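"""Read and write the wide flock-performance table.

Dialect: one row per flock, suffixed columns per age — ``bw_0 … bw_35``,
``fi_7 … fi_35``, ``fcr_7 … fcr_35``, ``wmort_7 … wmort_35``,
``cmort_7 … cmort_35`` — plus ``flock_id`` and ``sex``.  Delimited text
(comma by default, tab accepted), UTF-8, header mandatory, empty cells for
missing values.  Numeric values are stored to 3 decimal places, which
exceeds the precision at which such records are reported.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import DEFAULT_AGES, FlockRecord, SEXES, WeeklySeries

#: variables undefined at age 0 (cumulative quantities start with week 1)
_LATER_VARS = ("fi", "fcr", "wmort", "cmort")
_VAR_TO_FIELD = {
    "bw": "bw",
    "fi": "fi",
    "fcr": "fcr",
    "wmort": "week_mort",
    "cmort": "cum_mort",
}
PRECISION = 3


class FormatError(ValueError):
    """The file does not follow the flock-table dialect."""


class DatasetError(ValueError):
    """The file parses but is inconsistent as a dataset (e.g. duplicate IDs)."""


@dataclass
class RejectedRow:
    flock_id: str
    reason: str


def table_columns(ages: tuple[int, ...] = DEFAULT_AGES) -> list[str]:
    cols = ["flock_id", "sex"]
    cols += [f"bw_{a}" for a in ages]
    for var in _LATER_VARS:
        cols += [f"{var}_{a}" for a in ages[1:]]
    return cols


def read_flock_table(
    path: str | os.PathLike,
    sep: str = ",",
    ages: tuple[int, ...] = DEFAULT_AGES,
) -> tuple[list[FlockRecord], list[RejectedRow]]:
    """Read a flock table, validating each row.

    Returns ``(records, rejects)``: rows that fail validation (missing or
    non-numeric mandatory cells, inconsistent series) are collected with a
    reason instead of aborting the read.

    Raises ``FormatError`` for a missing mandatory column and
    ``DatasetError`` for duplicated flock IDs.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in table_columns(ages) if c not in df.columns]
    if missing:
        raise FormatError(f"missing mandatory column(s): {', '.join(missing)}")
    ids = df["flock_id"].tolist()
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise DatasetError(f"duplicate flock_id: {sorted(dupes)}")

    records: list[FlockRecord] = []
    rejects: list[RejectedRow] = []
    for _, row in df.iterrows():
        fid = row["flock_id"]
        sex = row["sex"].strip().lower()
        if sex not in SEXES:
            rejects.append(RejectedRow(fid, f"unknown sex {row['sex']!r}"))
            continue
        series = WeeklySeries(ages=ages)
        bad_cell = None
        for var, fieldname in _VAR_TO_FIELD.items():
            arr = getattr(series, fieldname)
            var_ages = ages if var == "bw" else ages[1:]
            offset = 0 if var == "bw" else 1
            for j, a in enumerate(var_ages):
                cell = row[f"{var}_{a}"].strip()
                if cell == "":
                    continue  # NaN already in place; completeness checked below
                try:
                    arr[j + offset] = float(cell)
                except ValueError:
                    bad_cell = f"non-numeric value {cell!r} in {var}_{a}"
                    break
            if bad_cell:
                break
        if bad_cell:
            rejects.append(RejectedRow(fid, bad_cell))
            continue
        probs = series.problems()
        if probs:
            rejects.append(RejectedRow(fid, "; ".join(dict.fromkeys(probs))))
            continue
        records.append(FlockRecord(flock_id=fid, sex=sex, series=series))
    return records, rejects


def records_to_frame(records: list[FlockRecord]) -> pd.DataFrame:
    """Flatten records into the wide one-row-per-flock layout."""
    ages = records[0].series.ages if records else DEFAULT_AGES
    rows = []
    for rec in records:
        row: dict[str, object] = {"flock_id": rec.flock_id, "sex": rec.sex}
        s = rec.series
        for a, v in zip(ages, s.bw):
            row[f"bw_{a}"] = round(float(v), PRECISION)
        for var in _LATER_VARS:
            vals = getattr(s, _VAR_TO_FIELD[var])
            for a, v in zip(ages[1:], vals[1:]):
                row[f"{var}_{a}"] = round(float(v), PRECISION) if np.isfinite(v) else np.nan
        rows.append(row)
    return pd.DataFrame(rows, columns=table_columns(ages))


def write_flock_table(
    records: list[FlockRecord],
    path: str | os.PathLike,
    sep: str = ",",
) -> None:
    """Write records so that ``read_flock_table`` round-trips them losslessly
    at the declared 3-decimal precision.  An empty list yields a header-only
    file."""
    df = records_to_frame(records)
    df.to_csv(path, sep=sep, index=False, float_format=f"%.{PRECISION}f")


def clean_flocks(
    records: list[FlockRecord],
) -> tuple[list[FlockRecord], list[RejectedRow]]:
    """Split records into (kept, dropped): kept flocks have complete,
    internally consistent weekly data at every age; dropped carry reasons.
    Idempotent — cleaning the kept list again drops nothing."""
    kept: list[FlockRecord] = []
    dropped: list[RejectedRow] = []
    for rec in records:
        probs = rec.series.problems()
        if probs:
            dropped.append(RejectedRow(rec.flock_id, "; ".join(dict.fromkeys(probs))))
        else:
            kept.append(rec)
    return kept, dropped
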