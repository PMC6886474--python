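"""Chunked consensus screening of large compound libraries.

A panel of trained models scores the library chunk by chunk; a compound is
a hit only when every model's active probability strictly exceeds the
cutoff (default 0.9).  Hits are annotated with their nearest-neighbor
Tanimoto similarity to the training actives, computed over the shared
binary (fingerprint-bit) columns only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from ._errors import ConfigurationError, DataError, SchemaError, StageError
from .classify import TrainedModel, predict_proba
from .table import BINARY, FeatureTable


@dataclass(frozen=True)
class ConsensusConfig:
    prob_threshold: float = 0.9
    require_unanimous: bool = True
    min_votes: Optional[int] = None  # used when require_unanimous is off
    chunk_size: int = 250_000

    def __post_init__(self):
        if not 0 < self.prob_threshold < 1:
            raise ConfigurationError("prob_threshold must lie in (0, 1)")
        if self.chunk_size < 1:
            raise ConfigurationError("chunk_size must be >= 1")
        if not self.require_unanimous and (self.min_votes is None or self.min_votes < 1):
            raise ConfigurationError(
                "non-unanimous mode requires min_votes >= 1"
            )


@dataclass(frozen=True)
class ScreeningSummary:
    n_screened: int
    n_hits: int
    hit_rate_pct: float


def consensus_vote(probs: Sequence[float], config: ConsensusConfig) -> bool:
    """Hit iff every probability (or ``min_votes`` of them) is strictly
    above the threshold."""
    probs = np.asarray(probs, float)
    if probs.size == 0:
        raise ConfigurationError("consensus_vote needs at least one probability")
    votes = int((probs > config.prob_threshold).sum())
    if config.require_unanimous:
        return votes == probs.size
    return votes >= config.min_votes


def tanimoto(a: Sequence[float], b: Sequence[float]) -> float:
    """|a AND b| / |a OR b| over binary vectors; 0 when both are all-zero."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ConfigurationError("tanimoto requires equal-length bit vectors")
    a = a.astype(bool)
    b = b.astype(bool)
    union = int(np.sum(a | b))
    if union == 0:
        return 0.0
    return float(np.sum(a & b)) / union


def nearest_neighbor_similarity(
    query: Sequence[float], actives_bits: np.ndarray, active_ids: Sequence
) -> Tuple[object, float]:
    """Max Tanimoto of ``query`` over the rows of ``actives_bits``.

    Ties break to the earliest active row.
    """
    q = np.asarray(query).astype(bool)
    A = np.asarray(actives_bits).astype(bool)
    inter = (A & q).sum(axis=1)
    union = (A | q).sum(axis=1)
    sims = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    best = int(np.argmax(sims))  # first maximum
    return active_ids[best], float(sims[best])


def _active_bits(training_actives: FeatureTable, bit_cols: List[str]) -> np.ndarray:
    return training_actives.values(bit_cols)


def _chunk_iter(
    library: Union[FeatureTable, Iterable[FeatureTable]], chunk_size: int
) -> Iterator[FeatureTable]:
    if isinstance(library, FeatureTable):
        ids = library.data.index
        for start in range(0, library.n_rows, chunk_size):
            yield library.select_rows(ids[start : start + chunk_size])
    else:
        yield from library


def iter_screen_chunks(
    library: Union[FeatureTable, Iterable[FeatureTable]],
    models: List[TrainedModel],
    training_actives: FeatureTable,
    config: ConsensusConfig = ConsensusConfig(),
) -> Iterator[pd.DataFrame]:
    """Yield one result frame per chunk (input order preserved).

    Columns: one ``prob_<model name>`` per model, ``hit``, and for hits
    only ``nn_id`` / ``nn_similarity`` (NaN elsewhere).
    """
    if not models:
        raise ConfigurationError("screening requires at least one model")
    required = sorted({c for m in models for c in m.columns})
    bit_cols = [
        c for c in training_actives.columns if training_actives.col_kind[c] == BINARY
    ]
    if not bit_cols:
        raise ConfigurationError(
            "no binary fingerprint columns shared with the training actives"
        )
    active_bits = _active_bits(training_actives, bit_cols)
    active_ids = list(training_actives.data.index)
    model_names = [m.name or f"model{i}" for i, m in enumerate(models)]
    if len(set(model_names)) != len(model_names):
        model_names = [f"{n}_{i}" for i, n in enumerate(model_names)]

    for chunk_no, chunk in enumerate(_chunk_iter(library, config.chunk_size)):
        missing = [c for c in required if c not in chunk.data.columns]
        if missing:
            raise SchemaError(
                f"screening chunk {chunk_no} lacks required column(s): {missing}"
            )
        try:
            probs = np.column_stack(
                [predict_proba(m, chunk) for m in models]
            )
        except Exception as exc:  # noqa: BLE001 - annotate failing chunk
            raise StageError("screen", f"chunk {chunk_no} failed: {exc}") from exc
        hits = (
            (probs > config.prob_threshold).all(axis=1)
            if config.require_unanimous
            else (probs > config.prob_threshold).sum(axis=1) >= config.min_votes
        )
        out = pd.DataFrame(
            probs, index=chunk.data.index, columns=[f"prob_{n}" for n in model_names]
        )
        out["hit"] = hits
        out["nn_id"] = pd.Series(pd.NA, index=out.index, dtype=object)
        out["nn_similarity"] = np.nan
        if hits.any():
            q_bits = chunk.values(bit_cols)
            for row in np.flatnonzero(hits):
                nn_id, sim = nearest_neighbor_similarity(
                    q_bits[row], active_bits, active_ids
                )
                out.iloc[row, out.columns.get_loc("nn_id")] = nn_id
                out.iloc[row, out.columns.get_loc("nn_similarity")] = sim
        yield out


def screen_library(
    library: Union[FeatureTable, Iterable[FeatureTable]],
    models: List[TrainedModel],
    training_actives: FeatureTable,
    config: ConsensusConfig = ConsensusConfig(),
) -> Tuple[pd.DataFrame, ScreeningSummary]:
    """Screen a library and return (results frame, summary)."""
    frames = list(iter_screen_chunks(library, models, training_actives, config))
    if not frames:
        raise DataError("screening library is empty")
    results = pd.concat(frames, axis=0)
    n = len(results)
    n_hits = int(results["hit"].sum())
    return results, ScreeningSummary(
        n_screened=n, n_hits=n_hits, hit_rate_pct=hit_rate(n_hits, n)
    )


def hit_rate(n_hits: int, n_screened: int) -> float:
    """Percentage of screened compounds called hits, to 3 significant figures."""
    if n_screened < 1:
        raise ConfigurationError("n_screened must be >= 1")
    if not 0 <= n_hits <= n_screened:
        raise ConfigurationError("need 0 <= n_hits <= n_screened")
    pct = 100.0 * n_hits / n_screened
    if pct == 0.0:
        return 0.0
    return float(f"{pct:.3g}")
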