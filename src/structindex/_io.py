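"""Delimited-text readers for point clouds and features."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_point_cloud", "read_feature", "read_distance_matrix"]


def _read_table(path) -> pd.DataFrame:
    """Read CSV/TSV with auto-detected delimiter and optional header.

    The header row is detected by a fully non-numeric first row; numeric
    parsing is locale-independent (period decimal separator).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if "\t" in first else ","

    def _is_number(x) -> bool:
        try:
            float(x)
            return True
        except (TypeError, ValueError):
            return False

    has_header = not any(_is_number(v) for v in first.strip().split(sep))
    return pd.read_csv(path, sep=sep, header=0 if has_header else None)


def read_point_cloud(path) -> np.ndarray:
    """N x D coordinate matrix from delimited text (one row per point)."""
    df = _read_table(path)
    try:
        arr = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric value in point cloud file {path}: {exc}")
    if not np.all(np.isfinite(arr)):
        bad = np.argwhere(~np.isfinite(arr))[0]
        raise ValueError(
            f"non-finite coordinate at row {bad[0] + 1}, column {bad[1] + 1} "
            f"of {path}"
        )
    return arr


def read_feature(path, categorical: bool = False):
    """Feature column(s): (N,) scalars or labels, or (N, m) vector feature."""
    df = _read_table(path)
    if categorical:
        if df.shape[1] != 1:
            raise ValueError("categorical feature must be a single column")
        return df.iloc[:, 0].astype(str).to_numpy()
    try:
        arr = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(
            f"non-numeric value in feature file {path} "
            f"(use --categorical for label features): {exc}"
        )
    return arr[:, 0] if arr.shape[1] == 1 else arr


def read_distance_matrix(path) -> np.ndarray:
    """Square N x N distance matrix from delimited text."""
    d = read_point_cloud(path)
    if d.shape[0] != d.shape[1]:
        raise ValueError(
            f"distance matrix in {path} is {d.shape[0]} x {d.shape[1]}, "
            "expected square"
        )
    return d
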