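"""Reading and writing score tables and reports.

Score tables are delimited long-format text: a header row with one column
per facet and a final ``score`` column, UTF-8, comma or tab delimited
(auto-detected).  Reports are written as delimited tables (for humans and
plotting) and JSON documents (machine-readable, byte-stable across runs).
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .design import Design
from .errors import DataError
from .gstudy import SCORE_COLUMN, validate_scores


def _detect_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_scores(path, design: Design | None = None) -> pd.DataFrame:
    """Read a long-format score table; validate against ``design`` if given.

    Malformed numeric cells are reported with their file line number
    (header = line 1).  An empty file raises a "no data" error rather than
    returning a zero-row table.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if len(lines) <= 1:
        raise DataError(f"no data in score table {path}")
    sep = _detect_delimiter(lines[0])
    df = pd.read_csv(path, sep=sep, dtype=str, skip_blank_lines=True)
    if SCORE_COLUMN not in df.columns:
        raise DataError(f"{path}: missing required column {SCORE_COLUMN!r}")
    numeric = pd.to_numeric(df[SCORE_COLUMN], errors="coerce")
    bad = numeric.isna() & df[SCORE_COLUMN].notna()
    if bad.any():
        row = int(df.index[bad][0])
        raise DataError(
            f"{path} line {row + 2}: score {df[SCORE_COLUMN].iloc[row]!r} "
            "is not numeric"
        )
    if numeric.isna().any():
        row = int(df.index[numeric.isna()][0])
        raise DataError(f"{path} line {row + 2}: missing score")
    df[SCORE_COLUMN] = numeric
    for col in df.columns:
        if col != SCORE_COLUMN:
            # facet labels: keep integers as integers when possible
            as_num = pd.to_numeric(df[col], errors="coerce")
            if as_num.notna().all() and (as_num == as_num.astype(int)).all():
                df[col] = as_num.astype(int)
    if design is not None:
        validate_scores(df, design)
    return df


def write_scores(scores: pd.DataFrame, path, sep: str = ",") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    scores.to_csv(path, sep=sep, index=False)


def write_table(df: pd.DataFrame, path, sep: str = ",") -> None:
    """Write a report table as delimited text (stable float formatting)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=False)


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def sha256_of(path) -> str:
    """Provenance hash of an input file."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
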