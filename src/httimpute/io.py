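"""Readers and writers for the plain-text interchange formats.

Expression and categorized matrices are TSV with sample IDs in the first row
and probe IDs in the first column.  Probe lists are one ID per line with
``#`` comments.  Sample metadata is a TSV keyed by sample ID.
"""
from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .matrix import (
    CategorizedMatrix,
    ExpressionMatrix,
    ProbeSet,
    _find_duplicates,
)


def _read_frame(path: str | Path, sep: str) -> pd.DataFrame:
    # Read the header line manually: pandas silently mangles duplicate
    # column names, which would hide a duplicate-sample error.
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    sample_ids = header[1:]
    dups = _find_duplicates(sample_ids)
    if dups:
        raise ValueError(f"{path}: duplicate sample ID(s): {dups[:5]}")
    df = pd.read_csv(path, sep=sep, index_col=0, header=0, float_precision="round_trip")
    df.columns = sample_ids
    dups = _find_duplicates(df.index)
    if dups:
        raise ValueError(f"{path}: duplicate probe ID(s): {dups[:5]}")
    return df


def _require_numeric(df: pd.DataFrame, path: str | Path) -> pd.DataFrame:
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                probe = df.index[bad.to_numpy().argmax()]
                raise ValueError(
                    f"{path}: non-numeric value {df.loc[probe, col]!r} at "
                    f"probe {probe!r}, sample {col!r}"
                )
            df[col] = coerced
    if df.isna().any().any():
        mask = df.isna().to_numpy()
        r, c = np.argwhere(mask)[0]
        raise ValueError(
            f"{path}: missing value at probe {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    return df


def read_expression_matrix(
    path: str | Path, sep: str = "\t", sample_meta: pd.DataFrame | None = None
) -> ExpressionMatrix:
    """Read a probe x sample TSV of relative expression values."""
    df = _require_numeric(_read_frame(path, sep), path)
    return ExpressionMatrix(df.astype(float), sample_meta)


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | Path, sep: str = "\t"
) -> None:
    matrix.data.to_csv(path, sep=sep, index_label="probe_id")


def read_categorized(
    path: str | Path, sep: str = "\t", sample_meta: pd.DataFrame | None = None
) -> CategorizedMatrix:
    """Read a ternary class matrix (cells in {-1, 0, 1})."""
    df = _require_numeric(_read_frame(path, sep), path)
    return CategorizedMatrix(df, sample_meta)


def write_categorized(matrix: CategorizedMatrix, path: str | Path, sep: str = "\t") -> None:
    matrix.classes.to_csv(path, sep=sep, index_label="probe_id")


def read_probe_list(path: str | Path, name: str | None = None) -> ProbeSet:
    """Read a plain-text probe list (one ID per line, '#' comments ignored)."""
    probes: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            probes.append(line)
    dups = _find_duplicates(probes)
    if dups:
        raise ValueError(f"{path}: duplicate probe ID(s): {dups[:5]}")
    return ProbeSet(name or Path(path).stem, frozenset(probes))


def write_probe_list(probe_set: ProbeSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in sorted(probe_set.probes):
            fh.write(p + "\n")


def read_sample_meta(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    meta = pd.read_csv(path, sep=sep, index_col=0)
    dups = _find_duplicates(meta.index)
    if dups:
        raise ValueError(f"{path}: duplicate sample ID(s): {dups[:5]}")
    return meta


def write_sample_meta(meta: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    meta.to_csv(path, sep=sep, index_label="sample_id")


def read_ordered_probe_list(path: str | Path) -> list[str]:
    """Like :func:`read_probe_list` but preserving file order (used for
    selection outputs, whose order records the greedy trajectory)."""
    probes: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            probes.append(line)
    dups = _find_duplicates(probes)
    if dups:
        raise ValueError(f"{path}: duplicate probe ID(s): {dups[:5]}")
    return probes


def write_ordered_probe_list(probes: Sequence[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in probes:
            fh.write(p + "\n")
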