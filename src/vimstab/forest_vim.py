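"""Random-forest contract and variable importance measures.

A random forest is an ensemble of CART-style trees, each grown on a
bootstrap resample of the data (bagging) with ``mtry`` candidate features
sampled uniformly at each node split (randomization).  Two standard
variable importance measures (VIMs) are computed from a fitted forest:

MDA (mean decrease accuracy)
    For each tree, the feature's values are permuted among that tree's
    out-of-bag (OOB) samples and the drop in the number of correct OOB
    predictions, divided by the OOB size, is averaged over trees.

MDG (mean decrease Gini)
    The total weighted Gini-impurity decrease of all node splits using the
    feature, summed within each tree and averaged over trees.

Both VIMs are stochastic: bagging and per-node feature sampling randomize
MDG, and MDA adds a third randomness source, the OOB permutations.  All
three are driven by explicit integer seeds so that every run is exactly
reproducible.

The tree learner is scikit-learn's :class:`~sklearn.tree.DecisionTreeClassifier`
(Gini criterion, grown to purity); bootstrap draws are performed here so
that per-tree bootstrap membership — and hence the OOB sets — is exact.
"""

from __future__ import annotations

from contextlib import contextmanager
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import sklearn
from sklearn.tree import DecisionTreeClassifier
from sklearn.tree import _classes as _sklearn_tree_classes

__all__ = [
    "Dataset",
    "ForestConfig",
    "NodeSplitRecord",
    "TreeRecord",
    "ForestModel",
    "ImportanceScores",
    "FeatureRanking",
    "fit_forest",
    "oob_accuracy",
    "mda_importance",
    "mdg_importance",
    "rank_features",
    "oob_from_bootstrap",
    "draw_bootstrap",
    "bootstrap_oob_fraction",
]


@dataclass(frozen=True)
class Dataset:
    """A tabular classification dataset.

    Parameters
    ----------
    X : ndarray of shape (n_sample, n_feature)
        Numeric feature matrix; no missing values.
    y : ndarray of shape (n_sample,)
        Class labels (at least two distinct classes).
    feature_ids : ndarray of shape (n_feature,)
        Stable integer identifiers, 1..d in column order.
    name : str
        Free-form dataset name used in reports.
    feature_names : tuple of str, optional
        Column names from the source file, aligned with ``feature_ids``.
    meta : dict, optional
        Generator-side ground truth (e.g. which columns are informative).
    """

    X: np.ndarray
    y: np.ndarray
    feature_ids: np.ndarray
    name: str = ""
    feature_names: tuple | None = None
    meta: dict | None = None

    def __post_init__(self):
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "feature_ids", np.asarray(self.feature_ids, dtype=int))
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        n, d = X.shape
        if n < 2:
            raise ValueError("need at least 2 samples")
        if d < 1:
            raise ValueError("need at least 1 feature")
        if y.shape != (n,):
            raise ValueError(f"y has shape {y.shape}, expected ({n},)")
        if not np.all(np.isfinite(X)):
            i, j = np.argwhere(~np.isfinite(X))[0]
            raise ValueError(f"non-finite feature value at row {i}, column {j}")
        if len(self.feature_ids) != d or len(set(self.feature_ids.tolist())) != d:
            raise ValueError("feature_ids must be unique, one per column")
        if len(np.unique(y)) < 2:
            raise ValueError("y must contain at least 2 classes")

    @property
    def n_sample(self) -> int:
        return self.X.shape[0]

    @property
    def n_feature(self) -> int:
        return self.X.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.y)

    @property
    def n_class(self) -> int:
        return len(self.classes)

    def subset(self, rows: np.ndarray, name: str | None = None) -> "Dataset":
        """Row-subset (e.g. a cross-validation training set)."""
        return Dataset(
            X=self.X[rows],
            y=self.y[rows],
            feature_ids=self.feature_ids,
            name=name if name is not None else self.name,
            feature_names=self.feature_names,
            meta=self.meta,
        )


@dataclass(frozen=True)
class ForestConfig:
    """Forest hyper-parameters: ``ntree`` trees, ``mtry`` split candidates, seed."""

    ntree: int
    mtry: int
    seed: int = 0

    def __post_init__(self):
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        if self.mtry < 1:
            raise ValueError("mtry must be >= 1")

    def with_seed(self, seed: int) -> "ForestConfig":
        return replace(self, seed=int(seed))


@dataclass(frozen=True)
class NodeSplitRecord:
    """One internal-node split: the feature used and the weighted Gini decrease.

    ``impurity_decrease`` is weighted by the fraction of (bootstrap) samples
    reaching the node, so per-tree decreases sum to a dimensionless total.
    """

    feature_id: int
    impurity_decrease: float


@dataclass(frozen=True)
class TreeRecord:
    """Contract a fitted tree must satisfy: deterministic prediction + split list."""

    predict: Callable[[np.ndarray], np.ndarray]
    splits: tuple


@dataclass(frozen=True)
class ForestModel:
    """A fitted forest with exact per-tree bootstrap/OOB membership."""

    trees: tuple
    oob_membership: tuple  # per tree, sorted sample indices absent from its bootstrap
    config: ForestConfig
    classes_: np.ndarray
    feature_ids: np.ndarray
    n_samples: int

    @property
    def ntree(self) -> int:
        return len(self.trees)


@dataclass(frozen=True)
class ImportanceScores:
    """Per-feature importance values from a single VIM run."""

    method: str  # "MDA" or "MDG"
    feature_ids: np.ndarray
    values: np.ndarray
    seed: int
    config: ForestConfig | None = None

    def __post_init__(self):
        if len(self.feature_ids) != len(self.values):
            raise ValueError("one score per feature required")

    def as_dict(self) -> dict:
        return {int(f): float(v) for f, v in zip(self.feature_ids, self.values)}


@dataclass(frozen=True)
class FeatureRanking:
    """Descending-importance ordering of the full feature set.

    ``order`` lists feature ids from most to least important; ``position``
    maps feature id -> 1-based rank and is the exact inverse of ``order``.
    """

    order: np.ndarray
    position: dict
    source: ImportanceScores | None = field(default=None, compare=False)

    @property
    def n_feature(self) -> int:
        return len(self.order)


def oob_from_bootstrap(bootstrap_indices: Sequence[int], n: int) -> np.ndarray:
    """Out-of-bag index set: samples absent from a bootstrap draw of size n."""
    mask = np.ones(n, dtype=bool)
    mask[np.asarray(bootstrap_indices, dtype=int)] = False
    return np.flatnonzero(mask)


def draw_bootstrap(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Draw one bootstrap sample of size n (with replacement) and its OOB set."""
    boot = rng.integers(0, n, size=n)
    return boot, oob_from_bootstrap(boot, n)


def bootstrap_oob_fraction(n: int, n_draws: int, seed: int) -> float:
    """Mean fraction of instances left out of a size-n bootstrap, over repeated draws.

    Converges to (1 - 1/n)^n -> e^{-1} ~ 0.368 for large n; this is the
    expected OOB share per tree under bagging.
    """
    rng = np.random.default_rng(seed)
    fracs = np.empty(n_draws)
    for i in range(n_draws):
        _, oob = draw_bootstrap(rng, n)
        fracs[i] = len(oob) / n
    return float(fracs.mean())


@contextmanager
def _skip_label_revalidation():
    """Skip sklearn's per-fit label type check while fitting many small trees.

    Dataset construction already guarantees a clean 1-D class-label vector;
    re-deriving the target type for every bootstrap resample costs more than
    building the tree itself at the sample sizes used here.  The original
    check is always restored.
    """
    original = _sklearn_tree_classes.check_classification_targets
    _sklearn_tree_classes.check_classification_targets = lambda y: None
    try:
        yield
    finally:
        _sklearn_tree_classes.check_classification_targets = original


def _fast_predict(clf: DecisionTreeClassifier) -> Callable[[np.ndarray], np.ndarray]:
    """Prediction closure accepting any numeric matrix (converted to the
    float32 layout the tree was trained on)."""

    def predict(A: np.ndarray) -> np.ndarray:
        return clf.predict(np.ascontiguousarray(A, dtype=np.float32), check_input=False)

    return predict


def _splits_from_sklearn(clf: DecisionTreeClassifier, feature_ids: np.ndarray) -> tuple:
    """Extract per-node weighted Gini decreases from a fitted sklearn tree."""
    t = clf.tree_
    left, right = t.children_left, t.children_right
    w, imp = t.weighted_n_node_samples, t.impurity
    total = w[0]
    out = []
    for k in range(t.node_count):
        if left[k] == -1:  # leaf
            continue
        dec = (w[k] * imp[k] - w[left[k]] * imp[left[k]] - w[right[k]] * imp[right[k]]) / total
        # tiny negative values are float round-off; the decrease is >= 0 by theory
        out.append(NodeSplitRecord(int(feature_ids[t.feature[k]]), max(float(dec), 0.0)))
    return tuple(out)


def fit_forest(data: Dataset, config: ForestConfig) -> ForestModel:
    """Fit a bagged ensemble of Gini trees with per-node mtry feature sampling.

    Each tree is trained on an independent bootstrap resample of size n drawn
    by this function's own RNG (so OOB membership is exact), grown to purity
    with ``mtry`` uniformly sampled candidate features per split.  Fully
    reproducible from ``config.seed``.
    """
    n, d = data.X.shape
    if config.mtry > d:
        raise ValueError(f"mtry={config.mtry} exceeds the number of features d={d}")
    if data.n_class < 2:
        raise ValueError("cannot fit a classifier on single-class data")

    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.ntree)
    # sklearn trees operate on float32 internally; converting once up front
    # lets every fit/predict skip re-validation of the same matrix
    X32 = np.ascontiguousarray(data.X, dtype=np.float32)
    trees, oobs = [], []
    with sklearn.config_context(
        skip_parameter_validation=True, assume_finite=True
    ), _skip_label_revalidation():
        for child in children:
            rng = np.random.default_rng(child)
            boot, oob = draw_bootstrap(rng, n)
            clf = DecisionTreeClassifier(
                criterion="gini",
                max_features=config.mtry,
                random_state=np.random.RandomState(int(rng.integers(2**31 - 1))),
            )
            clf.fit(X32[boot], data.y[boot], check_input=False)
            trees.append(
                TreeRecord(
                    predict=_fast_predict(clf),
                    splits=_splits_from_sklearn(clf, data.feature_ids),
                )
            )
            oobs.append(oob)
    return ForestModel(
        trees=tuple(trees),
        oob_membership=tuple(oobs),
        config=config,
        classes_=data.classes,
        feature_ids=data.feature_ids.copy(),
        n_samples=n,
    )


def oob_accuracy(model: ForestModel, data: Dataset) -> float:
    """Out-of-bag accuracy: each sample is predicted by majority vote of the
    trees that did not train on it; samples in no OOB set are excluded.

    Vote ties are broken toward the lowest class label (deterministic).
    """
    n = data.n_sample
    classes = model.classes_
    votes = np.zeros((n, len(classes)), dtype=np.int64)
    for tree, oob in zip(model.trees, model.oob_membership):
        if len(oob) == 0:
            continue
        pred = tree.predict(data.X[oob])
        ci = np.searchsorted(classes, pred)
        np.add.at(votes, (oob, ci), 1)
    evaluable = votes.sum(axis=1) > 0
    if not evaluable.any():
        raise ValueError("no sample is out-of-bag for any tree (zero evaluable samples)")
    pred = classes[np.argmax(votes[evaluable], axis=1)]
    return float(np.mean(pred == data.y[evaluable]))


def _used_feature_ids(tree: TreeRecord) -> list:
    seen, out = set(), []
    for s in tree.splits:
        if s.feature_id not in seen:
            seen.add(s.feature_id)
            out.append(s.feature_id)
    return out


def mda_importance(model: ForestModel, data: Dataset, seed: int) -> ImportanceScores:
    """Mean decrease accuracy (permutation importance on OOB samples).

    For each tree t and feature j the per-tree contribution is
    ``(#correct OOB predictions - #correct after permuting j among OOB_t) / |OOB_t|``,
    with one fresh permutation per (tree, feature) drawn from a sub-stream of
    ``seed``.  The score is the mean contribution over trees with a non-empty
    OOB set.  Features not used in any split of a tree leave its predictions
    unchanged, so their contribution for that tree is exactly zero.
    """
    fid_to_col = {int(f): c for c, f in enumerate(data.feature_ids)}
    contrib = np.zeros(data.n_feature)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(model.ntree)
    n_used_trees = 0
    for tree, oob, child in zip(model.trees, model.oob_membership, children):
        m = len(oob)
        if m == 0:
            continue  # tree contributes to no feature
        n_used_trees += 1
        rng = np.random.default_rng(child)
        Xo = data.X[oob].copy()
        yo = data.y[oob]
        before = int(np.sum(tree.predict(Xo) == yo))
        for fid in _used_feature_ids(tree):
            col = fid_to_col[fid]
            orig = Xo[:, col].copy()
            Xo[:, col] = orig[rng.permutation(m)]
            after = int(np.sum(tree.predict(Xo) == yo))
            Xo[:, col] = orig
            contrib[col] += (before - after) / m
    if n_used_trees == 0:
        raise ValueError("every tree has an empty OOB set; MDA undefined")
    return ImportanceScores(
        method="MDA",
        feature_ids=data.feature_ids.copy(),
        values=contrib / n_used_trees,
        seed=int(seed),
        config=model.config,
    )


def mdg_importance(model: ForestModel) -> ImportanceScores:
    """Mean decrease Gini: total weighted impurity decrease of all splits on a
    feature, summed within each tree and averaged over all trees.

    Deterministic given the fitted model; features never split on score 0.
    """
    fid_to_col = {int(f): c for c, f in enumerate(model.feature_ids)}
    total = np.zeros(len(model.feature_ids))
    for tree in model.trees:
        for s in tree.splits:
            total[fid_to_col[s.feature_id]] += s.impurity_decrease
    return ImportanceScores(
        method="MDG",
        feature_ids=model.feature_ids.copy(),
        values=total / model.ntree,
        seed=model.config.seed,
        config=model.config,
    )


def rank_features(scores: ImportanceScores) -> FeatureRanking:
    """Order features by descending importance; ties broken by ascending id."""
    fids = np.asarray(scores.feature_ids)
    order = fids[np.lexsort((fids, -np.asarray(scores.values, dtype=float)))]
    position = {int(f): r + 1 for r, f in enumerate(order)}
    return FeatureRanking(order=order, position=position, source=scores)
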