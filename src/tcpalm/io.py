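"""Reading and writing ThunderSTORM-dialect localization tables.

File convention (ThunderSTORM): header ``frame,"x [nm]","y [nm]",
"uncertainty [nm]"`` with 1-based frame numbers.  In memory, tables are
pandas DataFrames with columns ``frame`` (0-based int), ``x_nm``,
``y_nm`` and optionally ``uncertainty_nm`` / ``truth_cluster_id``,
sorted by frame with ties broken by x then y.  Unknown columns are
preserved untouched.
"""
from __future__ import annotations

import csv
import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_localizations", "write_localizations", "ParseError", "sort_table"]

#: maps recognised header spellings to canonical in-memory names
_ALIASES = {
    "frame": "frame",
    "x [nm]": "x_nm",
    "y [nm]": "y_nm",
    "x_nm": "x_nm",
    "y_nm": "y_nm",
    "x": "x_nm",
    "y": "y_nm",
    "uncertainty [nm]": "uncertainty_nm",
    "uncertainty_xy [nm]": "uncertainty_nm",
    "uncertainty_nm": "uncertainty_nm",
    "uncertainty": "uncertainty_nm",
    "truth_cluster_id": "truth_cluster_id",
}

_MANDATORY = ("frame", "x_nm", "y_nm")
_NUMERIC = ("frame", "x_nm", "y_nm", "uncertainty_nm", "truth_cluster_id")


class ParseError(ValueError):
    """Raised when a localization file cannot be interpreted."""


def sort_table(table: pd.DataFrame) -> pd.DataFrame:
    """Return the table sorted by (frame, x, y), index reset."""
    order = np.lexsort(
        (table["y_nm"].to_numpy(), table["x_nm"].to_numpy(), table["frame"].to_numpy())
    )
    return table.iloc[order].reset_index(drop=True)


def read_localizations(path: str | Path) -> pd.DataFrame:
    """Read a ThunderSTORM-dialect CSV into a localization table.

    Accepts quoted ThunderSTORM headers (``"x [nm]"``) or minimal
    ``frame,x,y`` headers; file frames are 1-based and converted to
    0-based.  Missing mandatory columns or non-numeric cells raise
    :class:`ParseError` naming the offending column or row.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    rename = {}
    for col in df.columns:
        key = col.strip().strip('"').lower()
        rename[col] = _ALIASES.get(key, col)
    df = df.rename(columns=rename)
    for col in _MANDATORY:
        if col not in df.columns:
            raise ParseError(f"{path.name}: missing mandatory column '{col}'")
    for col in df.columns:
        if col not in _NUMERIC:
            continue  # opaque payload columns stay as-is
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path.name}: non-numeric value {df[col].iloc[row]!r} in "
                f"column '{col}', data row {row + 1}"
            )
        df[col] = converted
    df["frame"] = df["frame"].astype(np.int64) - 1  # file is 1-based
    if (df["frame"] < 0).any():
        raise ParseError(f"{path.name}: frame numbers must be >= 1 in files")
    if "truth_cluster_id" in df.columns:
        df["truth_cluster_id"] = df["truth_cluster_id"].astype(np.int64)
    return sort_table(df)


def write_localizations(table: pd.DataFrame, path: str | Path) -> None:
    """Write a localization table as ThunderSTORM-dialect CSV.

    Emits the quoted ThunderSTORM header and 1-based frame numbers;
    ``truth_cluster_id`` (simulation ground truth) is appended when
    present.
    """
    path = Path(path)
    cols = ["frame", "x_nm", "y_nm"]
    header = ["frame", "x [nm]", "y [nm]"]
    if "uncertainty_nm" in table.columns:
        cols.append("uncertainty_nm")
        header.append("uncertainty [nm]")
    if "truth_cluster_id" in table.columns:
        cols.append("truth_cluster_id")
        header.append("truth_cluster_id")
    out = table[cols].copy()
    out["frame"] = out["frame"].astype(np.int64) + 1
    buf = _io.StringIO()
    writer = csv.writer(buf, quoting=csv.QUOTE_NONNUMERIC)
    writer.writerow(header)
    body = out.to_csv(index=False, header=False, lineterminator="\n")
    path.write_text(buf.getvalue() + body)
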