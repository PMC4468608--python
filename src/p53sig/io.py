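"""Readers and writers for the pipeline's tabular formats.

Expression matrices are TSV (features as rows, first column ``feature_id``,
samples as columns) or GCT 1.2 ("#1.2" version line, dimensions line,
Name/Description columns).  Annotation and calls are TSV; dose-response,
trajectory and compound tables are CSV.  All text is UTF-8 with '.'
decimals; writers emit floats with 6 significant digits.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_expression", "write_expression", "read_annotation",
    "write_annotation", "read_dose_response", "read_trajectories",
    "read_compounds", "read_calls", "write_table",
]

FLOAT_FMT = "%.6g"


class FormatError(ValueError):
    pass


def _check_expression(df: pd.DataFrame, path) -> pd.DataFrame:
    dup = df.index[df.index.duplicated()].unique()
    if len(dup):
        raise FormatError(f"{path}: duplicated feature id(s): {list(dup)[:5]}")
    dupc = df.columns[df.columns.duplicated()].unique()
    if len(dupc):
        raise FormatError(f"{path}: duplicated sample id(s): {list(dupc)[:5]}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError):
        for j, col in enumerate(df.columns):
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise FormatError(
                    f"{path}: non-numeric cell at feature {df.index[i]!r}, "
                    f"sample {col!r}: {df[col].iloc[i]!r}") from None
        raise
    if df.isna().any().any():
        i, j = np.argwhere(df.isna().to_numpy())[0]
        raise FormatError(f"{path}: missing value at feature "
                          f"{df.index[i]!r}, sample {df.columns[j]!r}")
    return df


def read_expression(path) -> pd.DataFrame:
    """Read an expression matrix from TSV or GCT 1.2 (sniffed)."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().rstrip("\n")
    if first.startswith("#1.2") or path.suffix.lower() == ".gct":
        with open(path, encoding="utf-8") as fh:
            version = fh.readline().strip()
            if not version.startswith("#1.2"):
                raise FormatError(f"{path}: unsupported GCT version {version!r}")
            dims = fh.readline().split()
            if len(dims) < 2:
                raise FormatError(f"{path}: malformed GCT dimensions line")
            n_rows, n_cols = int(dims[0]), int(dims[1])
            df = pd.read_csv(fh, sep="\t", index_col=0)
        df = df.drop(columns=["Description"], errors="ignore")
        if df.shape != (n_rows, n_cols):
            raise FormatError(
                f"{path}: GCT dimensions line says {n_rows}x{n_cols}, "
                f"found {df.shape[0]}x{df.shape[1]}")
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "feature_id"
    return _check_expression(df, path)


def write_expression(matrix: pd.DataFrame, path, fmt: str = "tsv") -> None:
    path = Path(path)
    if fmt == "gct" or path.suffix.lower() == ".gct":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("#1.2\n")
            fh.write(f"{matrix.shape[0]}\t{matrix.shape[1]}\n")
            out = matrix.copy()
            out.insert(0, "Description", "na")
            out.index.name = "Name"
            out.to_csv(fh, sep="\t", float_format=FLOAT_FMT)
    else:
        matrix.to_csv(path, sep="\t", float_format=FLOAT_FMT,
                      index_label="feature_id")


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str).set_index("sample_id")
    dup = df.index[df.index.duplicated()].unique()
    if len(dup):
        raise FormatError(f"{path}: duplicated sample id(s): {list(dup)[:5]}")
    bad = set(df.get("tp53_status", pd.Series(dtype=str)).dropna()) - {"WT", "MUT"}
    if bad:
        raise FormatError(f"{path}: tp53_status values outside WT/MUT: {bad}")
    return df


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index_label="sample_id")


def read_dose_response(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("sample_id", "ic50_um", "amax_pct"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return df


def read_trajectories(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("sample_id", "day", "pct_change"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return df


def read_compounds(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("compound_id", "target_class", "sample_id", "metric"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return df


def read_calls(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns or "call" not in df.columns:
        raise FormatError(f"{path}: calls table needs sample_id and call")
    return df


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    """Write a generic result table; TSV for .tsv, CSV otherwise."""
    sep = "\t" if str(path).endswith(".tsv") else ","
    df.to_csv(path, sep=sep, float_format=FLOAT_FMT, index=index)
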