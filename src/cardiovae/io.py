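"""Delimited-text readers and writers for omics matrices and annotations.

All matrices follow the convention samples-as-rows / features-as-columns,
with a header row of feature names and the first column holding sample ids.
Tab and comma delimiters are auto-detected. Parsing errors report the
offending line and column so malformed exports are easy to locate.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd


class MatrixFormatError(ValueError):
    """Raised when a delimited matrix file is malformed."""


def _detect_delimiter(header_line: str) -> str:
    # Tab wins if present; otherwise comma. A single-column file falls back
    # to tab, which is harmless for a one-token header.
    if "\t" in header_line:
        return "\t"
    if "," in header_line:
        return ","
    return "\t"


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a labelled numeric matrix from a tab- or comma-delimited file.

    Returns a DataFrame with sample ids as the index and feature names as
    columns, all values parsed as float64.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    MatrixFormatError
        On ragged rows (with the line number) or non-numeric cells (with
        1-based row and column coordinates of the matrix body).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"matrix file not found: {path}")
    with open(path, newline="") as fh:
        first = fh.readline()
        if not first.strip():
            raise MatrixFormatError(f"{path}: empty file")
        delim = _detect_delimiter(first)
        fh.seek(0)
        rows = list(csv.reader(fh, delimiter=delim))

    header = rows[0]
    ncol = len(header)
    feature_names = header[1:]
    sample_ids: list[str] = []
    body: list[list[float]] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue  # trailing blank line
        if len(row) != ncol:
            raise MatrixFormatError(
                f"{path}: ragged row at line {lineno} "
                f"(expected {ncol} fields, got {len(row)})"
            )
        sample_ids.append(row[0])
        vals = []
        for j, cell in enumerate(row[1:], start=1):
            try:
                vals.append(float(cell))
            except ValueError:
                raise MatrixFormatError(
                    f"{path}: non-numeric cell {cell!r} at row "
                    f"{lineno - 1}, column {j}"
                ) from None
        body.append(vals)

    return pd.DataFrame(
        np.asarray(body, dtype=np.float64), index=sample_ids, columns=feature_names
    )


def write_matrix(df: pd.DataFrame, path: str | Path, delimiter: str = "\t") -> None:
    """Write a labelled matrix; round-trips bit-exactly through read_matrix."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=delimiter, index_label="sample_id", float_format="%.17g")


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read the per-sample annotation table (sample_id, group, batch)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"annotation file not found: {path}")
    with open(path) as fh:
        delim = _detect_delimiter(fh.readline())
    ann = pd.read_csv(path, sep=delim, index_col=0, dtype=str)
    if "group" not in ann.columns:
        raise MatrixFormatError(f"{path}: annotation table lacks a 'group' column")
    return ann


def write_annotations(ann: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ann.to_csv(path, sep="\t", index_label="sample_id")
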