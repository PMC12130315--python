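"""TSV/JSON input-output helpers.

Dialect used throughout: tab-separated, UTF-8, one header row, first
column holds the entity identifier. Missing cells are empty fields.
Floats are written with ``%.10g`` so that identical inputs produce
byte-identical files (the determinism contract of the pipeline).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_profiles",
    "write_profiles",
    "read_sets",
    "write_sets",
    "write_json",
]

_FLOAT_FMT = "%.17g"  # full float64 round-trip precision


def read_matrix(path) -> pd.DataFrame:
    """Read a square matrix with matching row/column ids.

    Empty cells become NaN (missing pairs). Raises ``ValueError`` on
    row/column id mismatch or asymmetry beyond 1e-9.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    rows, cols = list(df.index), list(df.columns)
    if rows != cols:
        offenders = sorted(set(rows).symmetric_difference(cols)) or ["(ordering differs)"]
        raise ValueError(f"row/column ids do not match: {offenders[:10]}")
    v = df.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        asym = np.nanmax(np.abs(v - v.T)) if v.size else 0.0
    if np.isfinite(asym) and asym > 1e-9:
        raise ValueError(f"matrix in {path} is asymmetric (max deviation {asym:.3g})")
    return df


def write_matrix(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label="id")
    return path


def read_profiles(path) -> pd.DataFrame:
    """Entity x feature table of continuous values."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_profiles(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label="id")
    return path


def read_sets(path) -> dict[str, set[str]]:
    """Long-format (entity, item) table to a dict of item sets."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected at least two columns (entity, item)")
    ent, item = df.columns[:2]
    out: dict[str, set[str]] = {}
    for e, i in zip(df[ent], df[item]):
        out.setdefault(str(e), set()).add(str(i))
    return out


def write_sets(sets: dict[str, set[str]], path, columns=("id", "item")) -> Path:
    path = Path(path)
    rows = [(e, i) for e in sorted(sets) for i in sorted(sets[e])]
    pd.DataFrame(rows, columns=list(columns)).to_csv(path, sep="\t", index=False)
    return path


def write_json(obj, path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return path


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, set):
        return sorted(o)
    if isinstance(o, Path):
        return str(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
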