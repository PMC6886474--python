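"""Classifier training, hyperparameter optimization, and validation.

Three classifier kinds:

* ``DT`` — decision tree, Gini splits, depth bound, cost-complexity
  post-pruning.
* ``RF`` — random forest, information-gain (entropy) splits, bootstrap
  trees, per-node feature sampling of size ceil(sqrt(d)).
* ``NB`` — naive Bayes with Gaussian likelihoods on continuous columns and
  Laplace-smoothed Bernoulli likelihoods on binary columns.

Model selection follows the grid-search-by-cross-validated-AUC recipe:
stratified folds on the training portion, pooled out-of-fold predictions
scored by rank-based AUC, ties broken toward the cheaper model.  Metrics
(AUC, MCC) are implemented here rather than delegated, so they can be
checked against independent pair-counting oracles.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Tuple, Union

import numpy as np
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from ._errors import ConfigurationError, DataError, MetricError, SchemaError
from ._split import stratified_folds, stratified_split
from .cfs import FeatureSubset
from .table import BINARY, FeatureTable

CLASSIFIERS = ("DT", "RF", "NB")

#: spans the observed optima of the study's tuned models
DEFAULT_GRID = {
    "max_depth": tuple(range(2, 11)),
    "num_trees": (10, 25, 50, 75, 100, 150, 200, 250),
}

#: reduced grid for fast end-to-end harness runs
FAST_GRID = {"max_depth": (3, 6, 10), "num_trees": (25, 75)}


@dataclass(frozen=True)
class ModelSpec:
    classifier: str
    max_depth: Optional[int] = None
    num_trees: Optional[int] = None
    ccp_alpha: float = 0.005  # DT post-pruning strength
    bootstrap: bool = True  # RF only
    full_feature_sampling: bool = False  # RF only; disables sqrt(d) sampling
    feature_subset: Union[FeatureSubset, str, None] = "all"
    cv_auc: Optional[float] = field(default=None, compare=False)

    def __post_init__(self):
        if self.classifier not in CLASSIFIERS:
            raise ConfigurationError(
                f"unknown classifier {self.classifier!r}; expected one of {CLASSIFIERS}"
            )
        if self.max_depth is not None and self.max_depth < 1:
            raise ConfigurationError("max_depth must be >= 1")
        if self.classifier == "RF" and (self.num_trees is None or self.num_trees < 1):
            raise ConfigurationError("RF requires num_trees >= 1")

    @property
    def split_criterion(self) -> Optional[str]:
        return {"DT": "gini", "RF": "gain_ratio", "NB": None}[self.classifier]

    def columns_or_none(self) -> Optional[List[str]]:
        if isinstance(self.feature_subset, FeatureSubset):
            return list(self.feature_subset.columns)
        return None


@dataclass(frozen=True)
class SplitConfig:
    train_fraction: float = 0.65
    cv_folds: int = 10
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ConfigurationError("train_fraction must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ConfigurationError("cv_folds must be >= 2")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ConfigurationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class ValidationReport:
    auc: float
    mcc: float
    confusion: ConfusionCounts
    mode: str  # test_set | cross_validation


class _MixedNaiveBayes:
    """Gaussian likelihoods for continuous columns, Laplace-smoothed
    Bernoulli for binary columns; uniform-prior-free (empirical priors)."""

    _VAR_FLOOR = 1e-9

    def fit(self, X: np.ndarray, y: np.ndarray, is_binary: np.ndarray):
        self.is_binary = np.asarray(is_binary, bool)
        self.classes_ = np.array([0, 1])
        self.log_prior = np.log(
            np.array([(y == c).mean() for c in self.classes_])
        )
        self.mu = np.zeros((2, X.shape[1]))
        self.var = np.ones((2, X.shape[1]))
        self.p_bit = np.full((2, X.shape[1]), 0.5)
        for ci, c in enumerate(self.classes_):
            Xc = X[y == c]
            self.mu[ci] = Xc.mean(axis=0)
            self.var[ci] = np.maximum(Xc.var(axis=0), self._VAR_FLOOR)
            self.p_bit[ci] = (Xc.sum(axis=0) + 1.0) / (len(Xc) + 2.0)  # Laplace
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        n = X.shape[0]
        log_post = np.tile(self.log_prior, (n, 1))
        for ci in range(2):
            cont = ~self.is_binary
            if cont.any():
                mu, var = self.mu[ci, cont], self.var[ci, cont]
                ll = -0.5 * (
                    np.log(2 * np.pi * var) + (X[:, cont] - mu) ** 2 / var
                )
                log_post[:, ci] += ll.sum(axis=1)
            if self.is_binary.any():
                p = self.p_bit[ci, self.is_binary]
                xb = X[:, self.is_binary]
                log_post[:, ci] += (
                    xb * np.log(p) + (1 - xb) * np.log1p(-p)
                ).sum(axis=1)
        log_post -= log_post.max(axis=1, keepdims=True)
        post = np.exp(log_post)
        post /= post.sum(axis=1, keepdims=True)
        return post


@dataclass
class TrainedModel:
    spec: ModelSpec
    columns: List[str]
    estimator: object
    training_digest: str
    name: str = ""


# ----------------------------------------------------------------------
def split_train_test(
    table: FeatureTable, config: SplitConfig = SplitConfig()
) -> Tuple[FeatureTable, FeatureTable]:
    """Stratified train/test split; train gets floor(n * fraction) rows."""
    y = table.y()
    train_idx, test_idx = stratified_split(y, config.train_fraction, config.seed)
    ids = table.data.index
    return table.select_rows(ids[train_idx]), table.select_rows(ids[test_idx])


def _model_columns(table: FeatureTable, spec: ModelSpec) -> List[str]:
    cols = spec.columns_or_none()
    if cols is None:
        return list(table.columns)
    missing = [c for c in cols if c not in table.data.columns]
    if missing:
        raise SchemaError(f"missing feature column(s): {missing}")
    return cols


def train(table: FeatureTable, spec: ModelSpec, seed: int = 0) -> TrainedModel:
    """Fit one classifier on the table's labeled rows."""
    cols = _model_columns(table, spec)
    X = table.values(cols)
    y = table.y()
    if spec.classifier == "DT":
        est = DecisionTreeClassifier(
            criterion="gini",
            max_depth=spec.max_depth,
            ccp_alpha=spec.ccp_alpha,
            random_state=seed,
        ).fit(X, y)
    elif spec.classifier == "RF":
        d = len(cols)
        max_features = d if spec.full_feature_sampling else int(math.ceil(math.sqrt(d)))
        est = RandomForestClassifier(
            n_estimators=spec.num_trees,
            criterion="entropy",
            max_depth=spec.max_depth,
            max_features=max_features,
            bootstrap=spec.bootstrap,
            random_state=seed,
        ).fit(X, y)
    else:  # NB
        is_binary = np.array([table.col_kind[c] == BINARY for c in cols])
        est = _MixedNaiveBayes().fit(X, y, is_binary)
    digest = hashlib.sha256(
        (",".join(map(str, cols)) + table.digest()).encode()
    ).hexdigest()
    return TrainedModel(
        spec=spec, columns=cols, estimator=est, training_digest=digest, name=table.name
    )


def predict_proba(model: TrainedModel, table: FeatureTable) -> np.ndarray:
    """Per-row active-class probability."""
    missing = [c for c in model.columns if c not in table.data.columns]
    if missing:
        raise SchemaError(f"missing feature column(s): {missing}")
    X = table.values(model.columns)
    proba = model.estimator.predict_proba(X)
    classes = list(getattr(model.estimator, "classes_", [0, 1]))
    return proba[:, classes.index(1)]


# ----------------------------------------------------------------------
def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC with midrank tie handling."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise MetricError("AUC requires both classes present")
    ranks = rankdata(scores)  # midranks
    return float(
        (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    )


def mcc(confusion: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor is 0."""
    tp, tn, fp, fn = confusion.tp, confusion.tn, confusion.fp, confusion.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / math.sqrt(denom))


def confusion_at_threshold(
    probs: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> ConfusionCounts:
    pred = np.asarray(probs) >= threshold
    labels = np.asarray(labels, int)
    return ConfusionCounts(
        tp=int((pred & (labels == 1)).sum()),
        tn=int((~pred & (labels == 0)).sum()),
        fp=int((pred & (labels == 0)).sum()),
        fn=int((~pred & (labels == 1)).sum()),
    )


def evaluate_test(model: TrainedModel, table: FeatureTable) -> ValidationReport:
    """Test-set AUC, MCC (probability threshold 0.5), and confusion counts."""
    probs = predict_proba(model, table)
    y = table.y()
    conf = confusion_at_threshold(probs, y)
    return ValidationReport(
        auc=roc_auc(probs, y), mcc=mcc(conf), confusion=conf, mode="test_set"
    )


def cross_validate(
    table: FeatureTable, spec: ModelSpec, config: SplitConfig = SplitConfig()
) -> ValidationReport:
    """Stratified k-fold CV with pooled out-of-fold predictions.

    One AUC and one MCC are computed on the pooled predictions rather than
    averaged per fold.
    """
    y = table.y()
    folds = stratified_folds(y, config.cv_folds, config.seed)
    pooled = np.empty(len(y))
    ids = table.data.index
    all_rows = np.arange(len(y))
    for f, test_rows in enumerate(folds):
        train_rows = np.setdiff1d(all_rows, test_rows)
        model = train(table.select_rows(ids[train_rows]), spec, seed=config.seed + f)
        pooled[test_rows] = predict_proba(model, table.select_rows(ids[test_rows]))
    conf = confusion_at_threshold(pooled, y)
    return ValidationReport(
        auc=roc_auc(pooled, y), mcc=mcc(conf), confusion=conf, mode="cross_validation"
    )


def optimize_hyperparameters(
    table: FeatureTable,
    classifier: str,
    grid: Optional[Dict[str, Iterable[int]]] = None,
    config: SplitConfig = SplitConfig(),
    feature_subset: Union[FeatureSubset, str, None] = "all",
) -> ModelSpec:
    """Full grid search scored by pooled CV AUC.

    Ties break toward smaller ``num_trees`` then smaller ``max_depth``.
    Returns the winning spec with its CV AUC attached.
    """
    if classifier not in CLASSIFIERS:
        raise ConfigurationError(f"unknown classifier {classifier!r}")
    grid = dict(grid if grid is not None else DEFAULT_GRID)
    depths = list(grid.get("max_depth", (None,))) or [None]
    trees = list(grid.get("num_trees", DEFAULT_GRID["num_trees"]))
    if classifier != "RF":
        trees = [None]
    if classifier == "NB":
        depths = [None]
    if not depths or not trees:
        raise ConfigurationError("hyperparameter grid is empty")
    best: Optional[Tuple[float, float, float, ModelSpec]] = None
    for nt in trees:
        for md in depths:
            spec = ModelSpec(
                classifier=classifier,
                max_depth=md,
                num_trees=nt,
                feature_subset=feature_subset,
            )
            auc = cross_validate(table, spec, config).auc
            key = (-auc, nt if nt is not None else 0, md if md is not None else 0)
            if best is None or key < best[0]:
                best = (key, spec, auc)
    _, spec, auc = best
    return replace(spec, cv_auc=auc)
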