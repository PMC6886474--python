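"""Correlation-based feature subset selection (CFS).

A subset S of k features is scored by the merit heuristic

    merit(S) = k * rcf / sqrt(k + k (k - 1) * rff)

where rcf is the mean |Pearson| correlation between each member and the
{0,1}-encoded class, and rff the mean |Pearson| inter-correlation over all
unordered member pairs (0 for k = 1).  Correlation magnitudes are used
throughout, so merit rewards relevance and penalizes redundancy regardless
of sign.

The subset lattice is searched by four strategies — best-first with
backtracking, a generational genetic algorithm, geometric (binary-mask)
particle swarm optimization, and subset-size forward selection — plus an
exhaustive enumerator used as a testing oracle.  All stochastic searchers
are pure functions of (table, config) including the config seed.

Global tie-breaking: higher merit, then smaller subset, then
lexicographically smallest sorted column list.
"""

from __future__ import annotations

import heapq
import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import List, Optional, Sequence, Tuple

import numpy as np

from ._errors import ConfigurationError, DataError
from ._split import stratified_folds
from .table import FeatureTable

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# scores and configs
@dataclass(frozen=True)
class MeritScore:
    merit: float
    k: int
    mean_class_corr: float
    mean_inter_corr: float


@dataclass
class FeatureSubset:
    columns: List[str]
    score: MeritScore
    selector: str
    dataset_name: str = ""

    def sorted_columns(self) -> Tuple[str, ...]:
        return tuple(sorted(map(str, self.columns)))


@dataclass(frozen=True)
class BFConfig:
    patience: int = 5
    backtracking: bool = True

    def __post_init__(self):
        if self.patience < 1:
            raise ConfigurationError("patience must be >= 1")


@dataclass(frozen=True)
class GSConfig:
    generations: int = 20
    population: int = 20
    p_crossover: float = 0.6
    p_mutation: float = 0.33
    seed: int = 0

    def __post_init__(self):
        if self.generations < 1 or self.population < 1:
            raise ConfigurationError("generations and population must be >= 1")
        for p in (self.p_crossover, self.p_mutation):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class GPSOConfig:
    w1: float = 0.33
    w2: float = 0.33
    w3: float = 0.34
    particles: int = 20
    iterations: int = 20
    bit_flip_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        ws = (self.w1, self.w2, self.w3)
        if any(w < 0 for w in ws):
            raise ConfigurationError("convex weights must be >= 0")
        if abs(sum(ws) - 1.0) > 1e-9:
            raise ConfigurationError("w1 + w2 + w3 must equal 1 (within 1e-9)")
        if self.particles < 1 or self.iterations < 0:
            raise ConfigurationError("particles must be >= 1 and iterations >= 0")


@dataclass(frozen=True)
class SSFSConfig:
    top_k: int = 50
    folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.top_k < 1:
            raise ConfigurationError("top_k must be >= 1")
        if self.folds < 2:
            raise ConfigurationError("folds must be >= 2")


# ----------------------------------------------------------------------
# correlation machinery
def _abs_corr_with_class(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    yc = y - y.mean()
    sy = np.sqrt((yc**2).sum())
    Xc = X - X.mean(axis=0)
    sx = np.sqrt((Xc**2).sum(axis=0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = (Xc * yc[:, None]).sum(axis=0) / (sx * sy)
    r[~np.isfinite(r)] = 0.0  # zero-variance convention
    return np.abs(r)


def _abs_corr_matrix(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    sx = np.sqrt((Xc**2).sum(axis=0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = (Xc.T @ Xc) / np.outer(sx, sx)
    r[~np.isfinite(r)] = 0.0
    np.fill_diagonal(r, 1.0)
    return np.abs(r)


class MeritEvaluator:
    """Caches class and inter-feature correlation magnitudes for one table.

    All searchers score subsets through one evaluator, so a search over
    thousands of candidate subsets costs one O(n d^2) correlation pass.
    """

    def __init__(self, table: FeatureTable, columns: Optional[Sequence] = None):
        if table.labels is None:
            raise DataError("CFS requires activity labels")
        self.columns = list(columns) if columns is not None else list(table.columns)
        X = table.values(self.columns)
        y = table.y().astype(float)
        if np.all(y == y[0]):
            raise DataError("CFS requires both classes present")
        self.rcf = _abs_corr_with_class(X, y)
        self.rff = _abs_corr_matrix(X)
        self._index = {c: i for i, c in enumerate(self.columns)}

    @property
    def d(self) -> int:
        return len(self.columns)

    def score_from_sums(self, k: int, sum_rcf: float, sum_rff: float) -> MeritScore:
        rcf_bar = sum_rcf / k
        rff_bar = sum_rff / (k * (k - 1) / 2) if k > 1 else 0.0
        denom = np.sqrt(k + k * (k - 1) * rff_bar)
        return MeritScore(
            merit=float(k * rcf_bar / denom) if denom > 0 else 0.0,
            k=k,
            mean_class_corr=float(rcf_bar),
            mean_inter_corr=float(rff_bar),
        )

    def score_indices(self, idx: Sequence[int]) -> MeritScore:
        idx = list(idx)
        k = len(idx)
        if k == 0:
            raise ConfigurationError("cannot score an empty subset")
        sum_rcf = float(self.rcf[idx].sum())
        sum_rff = (
            float(self.rff[np.ix_(idx, idx)].sum() - k) / 2.0 if k > 1 else 0.0
        )
        return self.score_from_sums(k, sum_rcf, sum_rff)

    def score_mask(self, mask: np.ndarray) -> MeritScore:
        return self.score_indices(np.flatnonzero(mask))

    def score_columns(self, cols: Sequence) -> MeritScore:
        return self.score_indices([self._index[c] for c in cols])

    def subset(self, idx: Sequence[int], selector: str, name: str = "") -> FeatureSubset:
        idx = list(idx)
        return FeatureSubset(
            columns=[self.columns[i] for i in idx],
            score=self.score_indices(idx),
            selector=selector,
            dataset_name=name,
        )


def _tiebreak_key(score: MeritScore, names: Tuple[str, ...]):
    """Smaller key = better subset."""
    return (-score.merit, score.k, names)


def _names(evaluator: MeritEvaluator, idx) -> Tuple[str, ...]:
    return tuple(sorted(str(evaluator.columns[i]) for i in idx))


# ----------------------------------------------------------------------
# public operations
def class_feature_correlation(table: FeatureTable, col) -> float:
    """|Pearson| between one column and the {0,1} class (0 if constant)."""
    if table.labels is None:
        raise DataError("table has no activity labels")
    X = table.values([col])
    return float(_abs_corr_with_class(X, table.y().astype(float))[0])


def merit(table: FeatureTable, columns: Sequence) -> MeritScore:
    """Merit of a feature subset (see module docstring for the formula)."""
    columns = list(columns)
    if not columns:
        raise ConfigurationError("merit of an empty subset is undefined")
    if len(set(columns)) != len(columns):
        raise ConfigurationError("subset contains duplicate columns")
    ev = MeritEvaluator(table, columns=None)
    return ev.score_columns(columns)


def reduction_rate(n_before: int, n_selected: int) -> float:
    """(n_before - n_selected) / n_before."""
    if n_before < 1:
        raise ConfigurationError("n_before must be >= 1")
    if not 0 <= n_selected <= n_before:
        raise ConfigurationError("need 0 <= n_selected <= n_before")
    return (n_before - n_selected) / n_before


def exhaustive_search(
    table: FeatureTable, max_dim: int = 15, dataset_name: str = ""
) -> FeatureSubset:
    """Enumerate every non-empty subset; testing oracle for the searchers."""
    ev = MeritEvaluator(table)
    if ev.d > max_dim:
        raise ConfigurationError(
            f"{ev.d} columns exceed the exhaustive guard ({max_dim}); "
            "use a heuristic searcher or raise max_dim explicitly"
        )
    best_idx, best_key = None, None
    for k in range(1, ev.d + 1):
        for idx in combinations(range(ev.d), k):
            key = _tiebreak_key(ev.score_indices(idx), _names(ev, idx))
            if best_key is None or key < best_key:
                best_key, best_idx = key, idx
    return ev.subset(best_idx, "EXHAUSTIVE", dataset_name)


# ----------------------------------------------------------------------
def best_first_search(
    table: FeatureTable, config: BFConfig = BFConfig(), dataset_name: str = ""
) -> FeatureSubset:
    """Forward best-first over the subset lattice with backtracking.

    The open list is ordered by merit; the best open node is expanded by
    all single-column additions.  An expansion producing no improvement on
    the best merit seen counts against ``patience``; ``patience``
    consecutive such expansions terminate the search.  With backtracking
    off, only the best child of the current node stays open (greedy hill
    climb).
    """
    ev = MeritEvaluator(table)
    empty = frozenset()
    heap: list = []  # (key, node)
    visited = {empty}
    heapq.heappush(heap, ((-np.inf, 0, ()), empty))
    best_key, best_idx = None, None
    stale = 0
    while heap:
        _, node = heapq.heappop(heap)
        children = []
        for j in range(ev.d):
            if j in node:
                continue
            child = frozenset(node | {j})
            if child in visited:
                continue
            visited.add(child)
            key = _tiebreak_key(ev.score_indices(sorted(child)), _names(ev, child))
            children.append((key, child))
        improved = False
        for key, child in children:
            if best_key is None or key[0] < best_key[0]:  # strictly higher merit
                improved = True
            if best_key is None or key < best_key:
                best_key, best_idx = key, child
        if config.backtracking:
            for item in children:
                heapq.heappush(heap, item)
        elif children:
            heapq.heappush(heap, min(children))
        stale = 0 if improved else stale + 1
        if stale >= config.patience:
            break
    if best_idx is None:
        raise DataError("no candidate columns to search")
    return ev.subset(sorted(best_idx), "BF", dataset_name)


def genetic_search(
    table: FeatureTable, config: GSConfig = GSConfig(), dataset_name: str = ""
) -> FeatureSubset:
    """Generational GA over inclusion bitstrings; fitness = merit.

    Roulette (fitness-proportional) selection, single-point crossover,
    one-bit mutation, single-elite carryover; empty individuals are
    repaired to a random singleton.
    """
    ev = MeritEvaluator(table)
    rng = np.random.default_rng(config.seed)
    d = ev.d

    def repair(mask: np.ndarray) -> np.ndarray:
        if not mask.any():
            mask = mask.copy()
            mask[rng.integers(d)] = True
        return mask

    def key_of(mask: np.ndarray):
        idx = np.flatnonzero(mask)
        return _tiebreak_key(ev.score_indices(idx), _names(ev, idx))

    pop = [repair(rng.random(d) < 0.5) for _ in range(config.population)]
    keys = [key_of(m) for m in pop]
    best_i = min(range(len(pop)), key=lambda i: keys[i])
    best_mask, best_key = pop[best_i].copy(), keys[best_i]

    for _ in range(config.generations):
        fitness = np.array([-k[0] for k in keys])  # merit
        w = fitness - fitness.min() + 1e-12
        w = w / w.sum()
        new_pop = [best_mask.copy()]  # elitism
        while len(new_pop) < config.population:
            i, j = rng.choice(len(pop), size=2, p=w)
            a, b = pop[i].copy(), pop[j].copy()
            if d >= 2 and rng.random() < config.p_crossover:
                point = int(rng.integers(1, d))
                a2 = np.concatenate([a[:point], b[point:]])
                b2 = np.concatenate([b[:point], a[point:]])
                a, b = a2, b2
            for child in (a, b):
                if rng.random() < config.p_mutation:
                    bit = int(rng.integers(d))
                    child[bit] = ~child[bit]
                new_pop.append(repair(child))
                if len(new_pop) >= config.population:
                    break
        pop = new_pop
        keys = [key_of(m) for m in pop]
        gen_best = min(range(len(pop)), key=lambda i: keys[i])
        if keys[gen_best] < best_key:
            best_key, best_mask = keys[gen_best], pop[gen_best].copy()
    return ev.subset(np.flatnonzero(best_mask), "GS", dataset_name)


def gpso_search(
    table: FeatureTable, config: GPSOConfig = GPSOConfig(), dataset_name: str = ""
) -> FeatureSubset:
    """Geometric PSO in binary subset space.

    Position update is a three-parent mask recombination: each bit is
    inherited from the particle's current position with probability w1,
    from the global best with probability w2, and from the particle's own
    best with probability w3.
    """
    ev = MeritEvaluator(table)
    rng = np.random.default_rng(config.seed)
    d = ev.d

    def repair(mask: np.ndarray) -> np.ndarray:
        if not mask.any():
            mask = mask.copy()
            mask[rng.integers(d)] = True
        return mask

    def key_of(mask: np.ndarray):
        idx = np.flatnonzero(mask)
        return _tiebreak_key(ev.score_indices(idx), _names(ev, idx))

    pos = [repair(rng.random(d) < 0.5) for _ in range(config.particles)]
    pkeys = [key_of(m) for m in pos]
    pbest = [m.copy() for m in pos]
    pbest_keys = list(pkeys)
    g_i = min(range(len(pos)), key=lambda i: pbest_keys[i])
    gbest, gbest_key = pbest[g_i].copy(), pbest_keys[g_i]

    for _ in range(config.iterations):
        for i in range(config.particles):
            u = rng.random(d)
            new = np.where(
                u < config.w1, pos[i], np.where(u < config.w1 + config.w2, gbest, pbest[i])
            )
            if config.bit_flip_rate > 0:
                flips = rng.random(d) < config.bit_flip_rate
                new = new ^ flips
            new = repair(new.astype(bool))
            pos[i] = new
            key = key_of(new)
            if key < pbest_keys[i]:
                pbest_keys[i], pbest[i] = key, new.copy()
            if key < gbest_key:
                gbest_key, gbest = key, new.copy()
    return ev.subset(np.flatnonzero(gbest), "PSO", dataset_name)


# ----------------------------------------------------------------------
def _forward_path(ev: MeritEvaluator, pool: List[int]) -> List[List[int]]:
    """Greedy nested forward-selection path within ``pool``.

    Returns prefixes: path[s-1] is the chosen subset of size s.
    """
    chosen: List[int] = []
    remaining = list(pool)
    sum_rcf, sum_rff = 0.0, 0.0
    path: List[List[int]] = []
    while remaining:
        best_c, best_key = None, None
        for c in remaining:
            k = len(chosen) + 1
            s_rcf = sum_rcf + ev.rcf[c]
            s_rff = sum_rff + (ev.rff[c, chosen].sum() if chosen else 0.0)
            score = ev.score_from_sums(k, s_rcf, s_rff)
            key = _tiebreak_key(score, _names(ev, chosen + [c]))
            if best_key is None or key < best_key:
                best_key, best_c = key, c
        sum_rcf += ev.rcf[best_c]
        sum_rff += ev.rff[best_c, chosen].sum() if chosen else 0.0
        chosen = chosen + [best_c]
        remaining.remove(best_c)
        path.append(list(chosen))
    return path


def _ranked_pool(ev: MeritEvaluator, top_k: int) -> List[int]:
    order = sorted(
        range(ev.d), key=lambda j: (-ev.rcf[j], str(ev.columns[j]))
    )
    return order[:top_k]


def ssfs_search(
    table: FeatureTable, config: SSFSConfig = SSFSConfig(), dataset_name: str = ""
) -> FeatureSubset:
    """Subset-size forward selection.

    Columns are ranked by class correlation and the top ``top_k`` form the
    search space.  A greedy forward path records the best subset at every
    size; the final size is chosen by mean held-out merit over stratified
    cross-validation folds (per fold, correlations and the forward path
    are recomputed on the training portion and the size-s subset is scored
    on the held-out portion), taking the smallest size within one standard
    error of the maximum.
    """
    ev = MeritEvaluator(table)
    top_k = config.top_k
    if top_k > ev.d:
        logger.warning("top_k=%d exceeds %d available columns; clamping", top_k, ev.d)
        top_k = ev.d
    pool = _ranked_pool(ev, top_k)
    full_path = _forward_path(ev, pool)

    y = table.y()
    folds = stratified_folds(y, config.folds, config.seed)
    all_rows = np.arange(table.n_rows)
    heldout = np.zeros((config.folds, len(full_path)))
    for f, test_rows in enumerate(folds):
        train_rows = np.setdiff1d(all_rows, test_rows)
        train_ev = MeritEvaluator(table.select_rows(table.data.index[train_rows]))
        test_ev = MeritEvaluator(table.select_rows(table.data.index[test_rows]))
        fold_path = _forward_path(train_ev, _ranked_pool(train_ev, top_k))
        for s in range(len(full_path)):
            subset = fold_path[min(s, len(fold_path) - 1)]
            heldout[f, s] = test_ev.score_indices(subset).merit
    mean_heldout = heldout.mean(axis=0)
    best = int(np.argmax(mean_heldout))
    # one-standard-error rule: held-out merit on small folds is noisy and
    # upward-biased for larger subsets, so prefer the smallest size whose
    # mean is within one SE of the best
    se = heldout[:, best].std(ddof=1) / np.sqrt(config.folds)
    s_star = int(np.argmax(mean_heldout >= mean_heldout[best] - se))
    return ev.subset(sorted(full_path[s_star]), "SSFS", dataset_name)


SEARCHERS = {
    "BF": lambda t, name="", **kw: best_first_search(t, BFConfig(**kw), name),
    "GS": lambda t, name="", **kw: genetic_search(t, GSConfig(**kw), name),
    "PSO": lambda t, name="", **kw: gpso_search(t, GPSOConfig(**kw), name),
    "SSFS": lambda t, name="", **kw: ssfs_search(t, SSFSConfig(**kw), name),
}
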