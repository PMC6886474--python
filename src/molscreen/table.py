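"""The compound-by-feature table that every pipeline stage consumes.

A :class:`FeatureTable` wraps a numeric :class:`pandas.DataFrame` (rows =
compounds, columns = features) together with per-column kinds (``binary``
fingerprint bits vs ``continuous`` descriptors) and optional per-row
metadata: activity labels, IC50 values in micromolar, and a row source tag
distinguishing assayed compounds from presumed-inactive decoys.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from ._errors import DataError, SchemaError

BINARY = "binary"
CONTINUOUS = "continuous"

ACTIVE = "active"
INACTIVE = "inactive"

#: row-source tag for decoy rows (pre-labeled inactive, no IC50)
DECOY = "decoy"
#: row-source tag for assayed (potentially active) rows
ASSAYED = "assayed"


@dataclass
class FeatureTable:
    """Compound x feature matrix with typed columns and optional labels.

    Parameters
    ----------
    data
        Numeric matrix; index = unique compound ids, columns = unique
        feature ids.
    col_kind
        Per-column kind, ``"binary"`` or ``"continuous"``, indexed like
        ``data.columns``.
    labels
        Optional per-row class, ``"active"`` / ``"inactive"``; when present
        must cover every row.
    ic50
        Optional per-row IC50 in uM; NaN marks absence (decoys).
    source
        Optional per-row provenance tag (``"assayed"`` / ``"decoy"``).
    """

    data: pd.DataFrame
    col_kind: pd.Series
    labels: Optional[pd.Series] = None
    ic50: Optional[pd.Series] = None
    source: Optional[pd.Series] = None
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise DataError(f"duplicate row id: {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise DataError(f"duplicate column id: {dup!r}")
        self.col_kind = self.col_kind.reindex(self.data.columns)
        if self.col_kind.isna().any():
            missing = self.col_kind.index[self.col_kind.isna()][0]
            raise SchemaError(f"column {missing!r} has no declared kind")
        bad = set(self.col_kind.unique()) - {BINARY, CONTINUOUS}
        if bad:
            raise SchemaError(f"unknown column kind(s): {sorted(bad)}")
        if not all(np.issubdtype(dt, np.number) for dt in self.data.dtypes):
            raise DataError("feature matrix must be numeric")
        bin_cols = self.binary_columns
        if len(bin_cols):
            vals = self.data[bin_cols].to_numpy()
            ok = np.isin(vals, (0.0, 1.0)) | np.isnan(vals)
            if not ok.all():
                j = np.argwhere(~ok)[0]
                raise DataError(
                    f"binary column {bin_cols[j[1]]!r} contains a value "
                    f"other than 0/1 at row {self.data.index[j[0]]!r}"
                )
        for attr in ("labels", "ic50", "source"):
            s = getattr(self, attr)
            if s is not None:
                setattr(self, attr, s.reindex(self.data.index))
        if self.labels is not None:
            if self.labels.isna().any():
                row = self.labels.index[self.labels.isna()][0]
                raise DataError(f"label missing for row {row!r}")
            bad = set(self.labels.unique()) - {ACTIVE, INACTIVE}
            if bad:
                raise DataError(f"unknown label value(s): {sorted(bad)}")

    # ------------------------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_cols(self) -> int:
        return self.data.shape[1]

    @property
    def columns(self) -> list:
        return list(self.data.columns)

    @property
    def binary_columns(self) -> list:
        return list(self.col_kind.index[self.col_kind == BINARY])

    @property
    def continuous_columns(self) -> list:
        return list(self.col_kind.index[self.col_kind == CONTINUOUS])

    def y(self) -> np.ndarray:
        """Class vector encoded {active: 1, inactive: 0}."""
        if self.labels is None:
            raise DataError("table has no activity labels")
        return (self.labels == ACTIVE).to_numpy(dtype=int)

    def values(self, columns: Optional[Iterable] = None) -> np.ndarray:
        if columns is None:
            return self.data.to_numpy(dtype=float)
        columns = list(columns)
        missing = [c for c in columns if c not in self.data.columns]
        if missing:
            raise SchemaError(f"missing feature column(s): {missing}")
        return self.data[columns].to_numpy(dtype=float)

    # ------------------------------------------------------------------
    def select_columns(self, columns: Iterable) -> "FeatureTable":
        """New table restricted to ``columns`` (order as given)."""
        columns = list(columns)
        missing = [c for c in columns if c not in self.data.columns]
        if missing:
            raise SchemaError(f"missing feature column(s): {missing}")
        return FeatureTable(
            data=self.data[columns].copy(),
            col_kind=self.col_kind[columns].copy(),
            labels=None if self.labels is None else self.labels.copy(),
            ic50=None if self.ic50 is None else self.ic50.copy(),
            source=None if self.source is None else self.source.copy(),
            name=self.name,
        )

    def select_rows(self, index) -> "FeatureTable":
        return FeatureTable(
            data=self.data.loc[index].copy(),
            col_kind=self.col_kind.copy(),
            labels=None if self.labels is None else self.labels.loc[index].copy(),
            ic50=None if self.ic50 is None else self.ic50.loc[index].copy(),
            source=None if self.source is None else self.source.loc[index].copy(),
            name=self.name,
        )

    def with_labels(self, labels: pd.Series) -> "FeatureTable":
        return FeatureTable(
            data=self.data,
            col_kind=self.col_kind,
            labels=labels,
            ic50=self.ic50,
            source=self.source,
            name=self.name,
        )

    # ------------------------------------------------------------------
    def digest(self) -> str:
        """Content hash of the matrix + column ids, for provenance."""
        h = hashlib.sha256()
        h.update(",".join(map(str, self.data.columns)).encode())
        h.update(",".join(map(str, self.data.index)).encode())
        h.update(np.ascontiguousarray(self.data.to_numpy(dtype=float)).tobytes())
        if self.labels is not None:
            h.update(",".join(self.labels.astype(str)).encode())
        return h.hexdigest()

    def equals(self, other: "FeatureTable") -> bool:
        if not self.data.equals(other.data):
            return False
        if not self.col_kind.equals(other.col_kind):
            return False
        for a, b in (
            (self.labels, other.labels),
            (self.ic50, other.ic50),
            (self.source, other.source),
        ):
            if (a is None) != (b is None):
                return False
            if a is not None and not a.equals(b):
                return False
        return True
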