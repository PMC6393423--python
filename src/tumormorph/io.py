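"""Shared table I/O: the cohort CSV schema and byte-stable CSV writing."""

from __future__ import annotations

import hashlib
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

COHORT_HEADER = ["group", "animal_id", "day", "length_mm", "width_mm", "weight_g"]


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a long-format caliper table, validating schema and keys.

    The header must be exactly ``group,animal_id,day,length_mm,width_mm,weight_g``
    (comma separator, decimal point, UTF-8; weight_g may be empty). Rows with
    length < width are kept but flagged with a warning (caliper orientation
    slip); duplicate (group, animal_id, day) keys and non-numeric cells are
    errors that name the offending row (1-based, excluding the header).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=",", encoding="utf-8", dtype=str, keep_default_na=False)
    if list(df.columns) != COHORT_HEADER:
        raise ValueError(
            f"{path}: header {list(df.columns)} != expected {COHORT_HEADER}"
        )
    out = df.copy()
    for col, kind in [("day", int), ("length_mm", float), ("width_mm", float)]:
        vals = []
        for i, cell in enumerate(df[col]):
            try:
                vals.append(kind(cell))
            except ValueError:
                raise ValueError(f"{path}: row {i + 1}: non-numeric {col} value {cell!r}")
        out[col] = vals
    weights = []
    for i, cell in enumerate(df["weight_g"]):
        if cell.strip() == "":
            weights.append(np.nan)
        else:
            try:
                weights.append(float(cell))
            except ValueError:
                raise ValueError(f"{path}: row {i + 1}: non-numeric weight_g value {cell!r}")
    out["weight_g"] = weights

    dup = out.duplicated(subset=["group", "animal_id", "day"])
    if dup.any():
        i = int(np.flatnonzero(dup)[0])
        key = tuple(out.loc[i, ["group", "animal_id", "day"]])
        raise ValueError(f"{path}: row {i + 1}: duplicate (group, animal, day) key {key}")
    bad = out["length_mm"] < out["width_mm"]
    if bad.any():
        warnings.warn(
            f"{path}: {int(bad.sum())} row(s) with length < width "
            f"(first at row {int(np.flatnonzero(bad)[0]) + 1}); treated as swapped"
        )
    if ((out["length_mm"] <= 0) | (out["width_mm"] <= 0)).any():
        i = int(np.flatnonzero((out["length_mm"] <= 0) | (out["width_mm"] <= 0))[0])
        raise ValueError(f"{path}: row {i + 1}: non-positive caliper diameter")
    if (out["day"] < 0).any():
        i = int(np.flatnonzero(out["day"] < 0)[0])
        raise ValueError(f"{path}: row {i + 1}: negative day")
    return out


def write_csv(df: pd.DataFrame, path) -> Path:
    """Write a table with fixed column order and 6-significant-digit floats.

    The formatting is locale-free and deterministic, so re-running a pipeline
    with the same seed reproduces output files byte for byte.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def fmt(v):
        if isinstance(v, (float, np.floating)):
            if np.isnan(v):
                return ""
            return f"{v:.6g}"
        return str(v)

    lines = [",".join(df.columns)]
    for row in df.itertuples(index=False):
        lines.append(",".join(fmt(v) for v in row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def write_cohort_csv(df: pd.DataFrame, path) -> Path:
    return write_csv(df[COHORT_HEADER], path)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
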