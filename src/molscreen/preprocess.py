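"""Activity binarization and the two-stage feature filter.

Stage 1 removes columns whose post-normalization variance falls at or
below a threshold (default: exactly zero, i.e. constant columns).
Stage 2 removes, in a greedy left-to-right sweep, every column whose
Kendall tau-a magnitude with an earlier surviving column exceeds the
cutoff (default 0.9); the earlier column is kept, the later dropped.
Survivors are de-normalized back to their original scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from ._errors import ConfigurationError, DataError
from .table import ACTIVE, DECOY, INACTIVE, FeatureTable

#: the canonical activity cutoffs, in uM
CANONICAL_THRESHOLDS = {
    "SET01": 4.0,
    "SET02": 3.0,
    "SET03": 2.0,
    "SET04": 1.0,
    "SET05": 11.4,
}


@dataclass(frozen=True)
class ActivityThreshold:
    cutoff_um: float
    name: str

    def __post_init__(self):
        if self.cutoff_um <= 0:
            raise ConfigurationError("cutoff_um must be > 0")


def canonical_thresholds() -> List[ActivityThreshold]:
    return [ActivityThreshold(c, n) for n, c in CANONICAL_THRESHOLDS.items()]


@dataclass(frozen=True)
class CorrelationFilterConfig:
    tau_threshold: float = 0.9
    variance_threshold: float = 0.0

    def __post_init__(self):
        if not 0 < self.tau_threshold <= 1:
            raise ConfigurationError("tau_threshold must lie in (0, 1]")
        if self.variance_threshold < 0:
            raise ConfigurationError("variance_threshold must be >= 0")


@dataclass
class FilterReport:
    """Bookkeeping for both filter stages; conserves column counts."""

    n_initial: int
    n_removed_low_variance: int = 0
    n_removed_high_correlation: int = 0
    removed_low_variance: List[str] = field(default_factory=list)
    removed_pairs: List[Tuple[str, str, float]] = field(default_factory=list)

    @property
    def n_remaining(self) -> int:
        return (
            self.n_initial
            - self.n_removed_low_variance
            - self.n_removed_high_correlation
        )

    def to_frame(self) -> pd.DataFrame:
        """Audit rows: stage, column, reason, statistic."""
        rows = [
            ("low_variance", col, "variance<=threshold", np.nan)
            for col in self.removed_low_variance
        ] + [
            ("high_correlation", dropped, f"tau-a with {kept}", tau)
            for kept, dropped, tau in self.removed_pairs
        ]
        return pd.DataFrame(rows, columns=["stage", "column", "reason", "statistic"])


# ----------------------------------------------------------------------
def binarize_activity(table: FeatureTable, threshold: ActivityThreshold) -> FeatureTable:
    """Label rows active iff IC50 <= cutoff; decoys stay inactive."""
    if table.source is None:
        raise DataError("table has no __source column; cannot identify decoys")
    decoy = table.source == DECOY
    ic50 = table.ic50 if table.ic50 is not None else pd.Series(np.nan, index=table.data.index)
    missing = (~decoy) & ic50.isna()
    if missing.any():
        row = table.data.index[missing.to_numpy()][0]
        raise DataError(f"non-decoy row {row!r} has no IC50 value")
    active = (~decoy) & (ic50 <= threshold.cutoff_um)
    labels = pd.Series(
        np.where(active, ACTIVE, INACTIVE), index=table.data.index
    )
    out = table.with_labels(labels)
    out.name = threshold.name or table.name
    return out


def normalize_minmax(table: FeatureTable) -> Tuple[FeatureTable, Dict[str, Tuple[float, float]]]:
    """Rescale each column to [0, 1]; constant columns map to 0.

    Returns the normalized table and per-column (min, max) so retained
    columns can be de-normalized exactly.
    """
    data = table.data
    mins = data.min(axis=0)
    maxs = data.max(axis=0)
    span = maxs - mins
    constant = span == 0
    safe_span = span.where(~constant, 1.0)
    normed = (data - mins) / safe_span
    normed.loc[:, constant] = 0.0
    out = FeatureTable(
        data=normed,
        col_kind=table.col_kind.copy(),
        labels=table.labels,
        ic50=table.ic50,
        source=table.source,
        name=table.name,
    )
    ranges = {c: (float(mins[c]), float(maxs[c])) for c in data.columns}
    return out, ranges


def denormalize(table: FeatureTable, ranges: Dict[str, Tuple[float, float]]) -> FeatureTable:
    data = table.data.copy()
    for c in data.columns:
        lo, hi = ranges[c]
        if hi > lo:
            data[c] = data[c] * (hi - lo) + lo
        else:  # constant column was mapped to 0
            data[c] = lo
    return FeatureTable(
        data=data,
        col_kind=table.col_kind.copy(),
        labels=table.labels,
        ic50=table.ic50,
        source=table.source,
        name=table.name,
    )


def remove_low_variance(
    table: FeatureTable, config: CorrelationFilterConfig = CorrelationFilterConfig()
) -> Tuple[FeatureTable, FilterReport]:
    """Drop every column with variance <= ``variance_threshold``."""
    var = table.data.var(axis=0, ddof=0)
    keep = [c for c in table.data.columns if var[c] > config.variance_threshold]
    dropped = [c for c in table.data.columns if var[c] <= config.variance_threshold]
    report = FilterReport(
        n_initial=table.n_cols,
        n_removed_low_variance=len(dropped),
        removed_low_variance=list(dropped),
    )
    return table.select_columns(keep), report


# ----------------------------------------------------------------------
def kendall_tau_a(x, y) -> float:
    """Kendall tau-a: (concordant - discordant) / (n(n-1)/2).

    Tied pairs (in either variable) count as neither concordant nor
    discordant.  Exact integer pair counting via vectorized sign products.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigurationError("kendall_tau_a requires two equal-length vectors")
    n = x.size
    if n < 2:
        raise ConfigurationError("kendall_tau_a requires n >= 2")
    num = _concordant_minus_discordant(x, y)
    return float(num) / (n * (n - 1) // 2)


def _sign_matrix(x: np.ndarray) -> np.ndarray:
    return np.sign(x[:, None] - x[None, :]).astype(np.int8)


def _concordant_minus_discordant(x: np.ndarray, y: np.ndarray) -> int:
    sx = _sign_matrix(x)
    sy = _sign_matrix(y)
    return int(np.sum(sx.astype(np.int32) * sy)) // 2


def kendall_tau_a_matrix(values: np.ndarray) -> np.ndarray:
    """Pairwise tau-a over the columns of ``values`` (n rows, d columns)."""
    n, d = values.shape
    denom = n * (n - 1) // 2
    signs = [_sign_matrix(values[:, j]) for j in range(d)]
    out = np.eye(d)
    for i in range(d):
        si = signs[i].astype(np.int32)
        for j in range(i + 1, d):
            out[i, j] = out[j, i] = (int(np.sum(si * signs[j])) // 2) / denom
    return out


def remove_high_correlation(
    table: FeatureTable,
    config: CorrelationFilterConfig = CorrelationFilterConfig(),
    ranges: Optional[Dict[str, Tuple[float, float]]] = None,
) -> Tuple[FeatureTable, FilterReport]:
    """Greedy sweep dropping later columns with |tau-a| > threshold.

    When ``ranges`` from :func:`normalize_minmax` is supplied, surviving
    columns are de-normalized before being returned.
    """
    cols = list(table.data.columns)
    values = table.data.to_numpy(dtype=float)
    n = values.shape[0]
    denom = n * (n - 1) // 2
    signs: Dict[int, np.ndarray] = {}

    def sign_of(j: int) -> np.ndarray:
        if j not in signs:
            signs[j] = _sign_matrix(values[:, j])
        return signs[j]

    kept: List[int] = []
    pairs: List[Tuple[str, str, float]] = []
    for j in range(len(cols)):
        sj = sign_of(j)
        offender = None
        for i in kept:
            tau = (int(np.sum(sign_of(i).astype(np.int32) * sj)) // 2) / denom
            if abs(tau) > config.tau_threshold:
                offender = (cols[i], cols[j], float(tau))
                break
        if offender is None:
            kept.append(j)
        else:
            pairs.append(offender)
            signs.pop(j, None)
    report = FilterReport(
        n_initial=table.n_cols,
        n_removed_high_correlation=len(pairs),
        removed_pairs=pairs,
    )
    out = table.select_columns([cols[j] for j in kept])
    if ranges is not None:
        out = denormalize(out, {c: ranges[c] for c in out.data.columns})
    return out, report


def apply_filters(
    table: FeatureTable, config: CorrelationFilterConfig = CorrelationFilterConfig()
) -> Tuple[FeatureTable, FilterReport]:
    """normalize -> low-variance filter -> tau-a filter -> de-normalize."""
    normed, ranges = normalize_minmax(table)
    lv_table, lv_report = remove_low_variance(normed, config)
    out, hc_report = remove_high_correlation(lv_table, config, ranges=ranges)
    report = FilterReport(
        n_initial=table.n_cols,
        n_removed_low_variance=lv_report.n_removed_low_variance,
        n_removed_high_correlation=hc_report.n_removed_high_correlation,
        removed_low_variance=lv_report.removed_low_variance,
        removed_pairs=hc_report.removed_pairs,
    )
    assert report.n_remaining == out.n_cols
    return out, report
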