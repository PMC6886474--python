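"""Delimited-text reading/writing of feature tables.

Dialect: comma-separated, UTF-8, one header row.  Reserved column names
carry row metadata and never collide with feature ids:

``__id``        compound identifier (required on write, first column)
``__label``     activity class (``active`` / ``inactive``), optional
``__ic50_um``   IC50 in micromolar, optional (empty cell = absent)
``__source``    row provenance (``assayed`` / ``decoy``), optional

Column kinds are written to a JSON sidecar ``<path>.schema.json`` so that a
continuous column whose observed values happen to all be 0/1 survives a
round trip.  When the sidecar is absent, a column is typed binary iff every
observed value is 0 or 1.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from ._errors import DataError
from .table import ACTIVE, BINARY, CONTINUOUS, INACTIVE, FeatureTable

RESERVED = ("__id", "__label", "__ic50_um", "__source")


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".schema.json")


def write_feature_table(table: FeatureTable, path: Union[str, Path]) -> Path:
    """Write ``table`` as CSV plus a kind sidecar; returns the CSV path."""
    path = Path(path)
    out = pd.DataFrame(index=table.data.index)
    out["__id"] = table.data.index.astype(str)
    if table.labels is not None:
        out["__label"] = table.labels
    if table.ic50 is not None:
        out["__ic50_um"] = table.ic50
    if table.source is not None:
        out["__source"] = table.source
    out = pd.concat([out, table.data], axis=1)
    path.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False, float_format="%.17g")  # exact float64 round trip
    schema = {str(c): table.col_kind[c] for c in table.data.columns}
    _sidecar_path(path).write_text(json.dumps(schema, indent=0))
    return path


def _check_header(path: Path) -> list:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(",")
    seen = set()
    for name in header:
        if name in seen:
            raise DataError(f"{path}: duplicate column name {name!r} in header")
        seen.add(name)
    return header


def _frame_to_table(
    frame: pd.DataFrame, schema: Optional[dict], path: Path, name: str = ""
) -> FeatureTable:
    if "__id" not in frame.columns:
        raise DataError(f"{path}: missing required '__id' column")
    frame = frame.set_index(frame["__id"].astype(str)).drop(columns="__id")
    frame.index.name = None
    labels = ic50 = source = None
    if "__label" in frame.columns:
        labels = frame.pop("__label").astype(str)
        bad = set(labels.unique()) - {ACTIVE, INACTIVE}
        if bad:
            raise DataError(f"{path}: unknown label value(s) {sorted(bad)}")
    if "__ic50_um" in frame.columns:
        raw = frame.pop("__ic50_um")
        # python float() is correctly rounded; pandas' default parser is not
        ic50 = raw.map(lambda v: np.nan if pd.isna(v) or v == "" else float(v))
    if "__source" in frame.columns:
        source = frame.pop("__source").astype(str)
    feats = frame
    for col in feats.columns:
        converted = pd.to_numeric(feats[col], errors="coerce")
        bad = converted.isna() & feats[col].notna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1 header line
        elif converted.isna().any():
            line = int(np.flatnonzero(converted.isna().to_numpy())[0]) + 2
        else:
            feats[col] = feats[col].astype(np.float64)  # correctly-rounded parse
            continue
        raise DataError(f"{path}: non-numeric cell in column {col!r} (line {line})")
    if schema is not None:
        kinds = pd.Series({c: schema.get(str(c), CONTINUOUS) for c in feats.columns})
    else:
        kinds = pd.Series(
            {
                c: BINARY if feats[c].isin((0.0, 1.0)).all() else CONTINUOUS
                for c in feats.columns
            }
        )
    return FeatureTable(
        data=feats, col_kind=kinds, labels=labels, ic50=ic50, source=source, name=name
    )


def read_feature_table(path: Union[str, Path], name: str = "") -> FeatureTable:
    """Read a feature-table CSV (with optional kind sidecar)."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    _check_header(path)
    sidecar = _sidecar_path(path)
    schema = json.loads(sidecar.read_text()) if sidecar.exists() else None
    try:
        frame = pd.read_csv(path, dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise DataError(f"{path}: {exc}") from exc
    return _frame_to_table(frame, schema, path, name=name)


def iter_feature_table_chunks(
    path: Union[str, Path], chunk_size: int, name: str = ""
):
    """Yield :class:`FeatureTable` chunks of at most ``chunk_size`` rows."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    _check_header(path)
    sidecar = _sidecar_path(path)
    schema = json.loads(sidecar.read_text()) if sidecar.exists() else None
    for frame in pd.read_csv(path, dtype=str, chunksize=chunk_size):
        yield _frame_to_table(frame, schema, path, name=name)
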