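"""Reading and writing the dataset CSV dialect and JSON manifests.

The writer emits a canonical representation (numbers formatted with ``%.10g``)
so that write -> read -> write round-trips are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import COLUMNS, DatasetError, StudyDataset

__all__ = ["read_dataset", "write_dataset", "read_manifest", "write_manifest"]

_INT_COLS = ("ID", "OCC", "DVTYPE", "MDV", "SEX")


def _fmt(value, col):
    if col in _INT_COLS:
        return str(int(value))
    return format(float(value), ".10g")


def write_dataset(ds: StudyDataset, path, manifest_path=None) -> None:
    """Write records as canonical CSV; optionally write the manifest JSON."""
    path = Path(path)
    df = ds.records
    lines = [",".join(COLUMNS)]
    for row in df.itertuples(index=False):
        lines.append(",".join(_fmt(v, c) for v, c in zip(row, COLUMNS)))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    if manifest_path is not None:
        write_manifest(ds.manifest or {}, manifest_path)


def read_dataset(path, manifest_path=None) -> StudyDataset:
    """Read a dataset CSV, validating the header and every row.

    Numeric parsing errors are reported with 1-based row numbers (header is
    row 1).  Unknown columns warn; missing required columns fail.
    """
    path = Path(path)
    header = path.open(encoding="utf-8").readline().rstrip("\n")
    got = header.split(",")
    missing = [c for c in COLUMNS if c not in got]
    if missing:
        raise DatasetError(f"{path}: missing required column(s) {missing}; header was {got}")
    try:
        df = pd.read_csv(path, encoding="utf-8")
    except ValueError as err:
        raise DatasetError(f"{path}: {err}") from err
    for col in COLUMNS:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            rows = list(df.index[bad] + 2)
            raise DatasetError(f"{path}: non-numeric value(s) in {col} at row(s) {rows[:5]}")
        if df[col].isna().any():
            rows = list(df.index[df[col].isna()] + 2)
            raise DatasetError(f"{path}: missing value(s) in {col} at row(s) {rows[:5]}")
    manifest = read_manifest(manifest_path) if manifest_path else None
    try:
        return StudyDataset(df, manifest)
    except DatasetError as err:
        raise DatasetError(f"{path}: {err}") from err


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=_json_default) + "\n",
        encoding="utf-8",
    )


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)!r}")
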