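"""CSV round-trip for individual-level records.

Fixed header ``block,panel,plate,treatment,survived,size,fecundity,density``;
missing values are empty fields, never sentinel numbers.  Parsing is strict:
bad rows raise :class:`~multistress.errors.DataError` naming the offending
line number (1-based, counting the header as line 1).
"""

from __future__ import annotations

import csv
import io
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError

HEADER = ["block", "panel", "plate", "treatment", "survived", "size", "fecundity", "density"]


def write_records(records: pd.DataFrame, path: str | Path) -> None:
    """Write records to CSV with the fixed schema (UTF-8, empty = missing)."""
    out = records.copy()
    for col in HEADER:
        if col not in out.columns:
            out[col] = pd.NA
    out = out[HEADER]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(HEADER)
        for row in out.itertuples(index=False):
            writer.writerow([_format_value(col, v) for col, v in zip(HEADER, row)])


def _format_value(col: str, value) -> str:
    if value is pd.NA or value is None or (isinstance(value, float) and np.isnan(value)):
        return ""
    if col == "fecundity":
        return repr(float(value))
    return str(value)


def read_records(path: str | Path) -> pd.DataFrame:
    """Parse a records CSV back into the canonical DataFrame.

    Raises :class:`DataError` with a line number for schema violations:
    wrong header, wrong field count, non-binary ``survived``, non-integer
    counts, or negative density.
    """
    with open(path, encoding="utf-8") as fh:
        return _read_records_stream(fh, str(path))


def _read_records_stream(fh: io.TextIOBase, name: str) -> pd.DataFrame:
    reader = csv.reader(fh)
    try:
        header = next(reader)
    except StopIteration:
        raise DataError(f"{name}: empty file, expected header {','.join(HEADER)}")
    if header != HEADER:
        raise DataError(f"{name}, line 1: bad header {header!r}, expected {HEADER}")

    blocks, panels, plates, treatments = [], [], [], []
    survived, size, fecundity, density = [], [], [], []
    for lineno, row in enumerate(reader, start=2):
        if not row:
            continue
        if len(row) != len(HEADER):
            raise DataError(
                f"{name}, line {lineno}: expected {len(HEADER)} fields, got {len(row)}"
            )
        b, pa, pl, tr, sv, sz, fe, de = row
        blocks.append(_parse_int(b, "block", name, lineno))
        if not pa or not pl or not tr:
            raise DataError(f"{name}, line {lineno}: empty design coordinate")
        panels.append(pa)
        plates.append(pl)
        treatments.append(tr)
        sv_val = _parse_int(sv, "survived", name, lineno)
        if sv_val not in (0, 1):
            raise DataError(
                f"{name}, line {lineno}: survived must be 0 or 1, got {sv_val}"
            )
        survived.append(sv_val)
        size.append(pd.NA if sz == "" else _parse_int(sz, "size", name, lineno))
        fecundity.append(np.nan if fe == "" else _parse_float(fe, "fecundity", name, lineno))
        de_val = _parse_int(de, "density", name, lineno)
        if de_val < 0:
            raise DataError(f"{name}, line {lineno}: negative density {de_val}")
        density.append(de_val)

    return pd.DataFrame(
        {
            "block": pd.Series(blocks, dtype=int) if blocks else pd.Series([], dtype=int),
            "panel": pd.Series(panels, dtype=object),
            "plate": pd.Series(plates, dtype=object),
            "treatment": pd.Series(treatments, dtype=object),
            "survived": pd.Series(survived, dtype=int) if survived else pd.Series([], dtype=int),
            "size": pd.array(size, dtype="Int64"),
            "fecundity": pd.Series(fecundity, dtype=float),
            "density": pd.Series(density, dtype=int) if density else pd.Series([], dtype=int),
        }
    )


def _parse_int(text: str, col: str, name: str, lineno: int) -> int:
    try:
        return int(text)
    except ValueError:
        raise DataError(f"{name}, line {lineno}: {col} must be an integer, got {text!r}")


def _parse_float(text: str, col: str, name: str, lineno: int) -> float:
    try:
        return float(text)
    except ValueError:
        raise DataError(f"{name}, line {lineno}: {col} must be a number, got {text!r}")
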