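"""Seeded stratified partitioning shared by selection and validation."""

from __future__ import annotations

from typing import List

import numpy as np

from ._errors import ConfigurationError


def stratified_folds(y: np.ndarray, k: int, seed: int) -> List[np.ndarray]:
    """Deterministic stratified k-fold assignment.

    Rows of each class are shuffled with the seeded generator and dealt
    round-robin, so fold class proportions differ from the global ones by
    at most one row per class.  Returns a list of row-index arrays.
    """
    y = np.asarray(y)
    if k < 2:
        raise ConfigurationError("fold count must be >= 2")
    for cls in np.unique(y):
        if (y == cls).sum() < 1:
            raise ConfigurationError(f"class {cls!r} is empty")
    if k > len(y):
        raise ConfigurationError("fold count exceeds number of rows")
    rng = np.random.default_rng(seed)
    folds: List[list] = [[] for _ in range(k)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for pos, row in enumerate(idx):
            folds[pos % k].append(row)
    return [np.sort(np.asarray(f, dtype=int)) for f in folds]


def stratified_split(y: np.ndarray, train_fraction: float, seed: int):
    """Deterministic stratified two-way split.

    The train partition gets floor(n * fraction) rows overall, allocated
    across classes by largest remainder so per-class proportions track the
    global fraction as closely as integer counts allow.
    """
    y = np.asarray(y)
    if not 0 < train_fraction < 1:
        raise ConfigurationError("train_fraction must lie in (0, 1)")
    classes = np.unique(y)
    for cls in classes:
        if (y == cls).sum() < 2:
            raise ConfigurationError(
                f"class {cls!r} has fewer than 2 members; cannot stratify"
            )
    n_train = int(np.floor(len(y) * train_fraction))
    exact = {cls: (y == cls).sum() * train_fraction for cls in classes}
    base = {cls: int(np.floor(v)) for cls, v in exact.items()}
    leftover = n_train - sum(base.values())
    by_remainder = sorted(
        classes, key=lambda c: (-(exact[c] - base[c]), str(c))
    )
    for cls in by_remainder[:leftover]:
        base[cls] += 1
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for cls in classes:
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        train_idx.extend(idx[: base[cls]])
        test_idx.extend(idx[base[cls] :])
    return np.sort(np.asarray(train_idx)), np.sort(np.asarray(test_idx))
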