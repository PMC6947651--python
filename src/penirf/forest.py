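"""Weighted-split random forests.

CART trees with bootstrap resampling and *weighted* candidate-feature
sampling at every node: at each split, ``mtry`` distinct features are drawn
with probability proportional to a nonnegative weight vector, so that a
feature with weight zero is never considered anywhere in the forest.  This is
the primitive the iterative-reweighting loop (`penirf.irf`) is built on.

Forests are assembled from deterministically seeded trees: the seed of tree
``t`` is a pure function of ``(master_seed, t)``, never of how trees are
chunked over workers, so the aggregated forest — and its importance vector —
is bit-identical for any worker count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from joblib import Parallel, delayed
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin

from . import _kernels, _seeds
from .dataset import Dataset
from .exceptions import DataError, DegenerateWeightsError, ParameterError

TASKS = ("regression", "classification")


# ---------------------------------------------------------------------------
# containers


@dataclass
class TreeNode:
    """Nested view of one node, for inspection and tests."""

    n_samples: int
    prediction: float
    split_feature: int = -1
    split_threshold: float = 0.0
    impurity_decrease: float = 0.0
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.split_feature < 0


@dataclass
class Tree:
    """Flat-array CART tree (see `penirf._kernels.grow_tree`)."""

    feature: np.ndarray
    threshold: np.ndarray
    value: np.ndarray
    left: np.ndarray
    right: np.ndarray
    decrease: np.ndarray
    n_node: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.feature.size

    @property
    def root(self) -> TreeNode:
        return self._build(0)

    def _build(self, i: int) -> TreeNode:
        node = TreeNode(
            n_samples=int(self.n_node[i]),
            prediction=float(self.value[i]),
            split_feature=int(self.feature[i]),
            split_threshold=float(self.threshold[i]),
            impurity_decrease=float(self.decrease[i]),
        )
        if not node.is_leaf:
            node.left = self._build(int(self.left[i]))
            node.right = self._build(int(self.right[i]))
        return node

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.ascontiguousarray(X, dtype=np.float64)
        out = np.empty(X.shape[0], np.float64)
        _kernels.predict_tree(
            self.feature, self.threshold, self.left, self.right, self.value, X, out
        )
        return out


@dataclass
class Forest:
    """An ensemble of weighted-split CART trees."""

    trees: List[Tree]
    task: str
    mtry: int
    min_node_size: int
    master_seed: int
    feature_ids: Sequence[str] = None
    classes: Optional[np.ndarray] = None  # label values for class codes

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict(self, X)

    def feature_importances(self) -> np.ndarray:
        return impurity_importance(self)


@dataclass
class SplitDecision:
    feature: int
    threshold: float
    impurity_decrease: float


# ---------------------------------------------------------------------------
# operations


def resolve_mtry(mtry, n_features: int) -> int:
    """``None``/``"sqrt"`` -> floor(sqrt(p)), else validated integer."""
    if mtry is None or mtry == "sqrt":
        return max(1, int(math.floor(math.sqrt(n_features))))
    mtry = int(mtry)
    if mtry < 1:
        raise ParameterError(f"mtry must be >= 1, got {mtry}")
    return min(mtry, n_features)


def resolve_min_node_size(min_node_size, task: str) -> int:
    if min_node_size is None:
        return 5 if task == "regression" else 1
    min_node_size = int(min_node_size)
    if min_node_size < 1:
        raise ParameterError(f"min_node_size must be >= 1, got {min_node_size}")
    return min_node_size


def _check_weights(weights, n_features: int) -> np.ndarray:
    if weights is None:
        return np.ones(n_features, np.float64)
    w = np.asarray(weights, dtype=np.float64)
    if w.shape != (n_features,):
        raise ParameterError(
            f"feature weights have shape {w.shape}, expected ({n_features},)"
        )
    if (w < 0).any():
        raise ParameterError("feature weights must be nonnegative")
    if not (w > 0).any():
        raise DegenerateWeightsError("all feature-sampling weights are zero")
    return w


def sample_candidate_features(weights, mtry: int, rng_state) -> np.ndarray:
    """Distinct feature indices drawn proportionally to ``weights``.

    ``rng_state`` is either an integer seed or a 1-element uint64 state array
    (which is advanced in place, so repeated calls give fresh draws).
    """
    w = _check_weights(np.asarray(weights, dtype=np.float64), len(weights))
    if int(mtry) < 1:
        raise ParameterError(f"mtry must be >= 1, got {mtry}")
    if isinstance(rng_state, np.ndarray):
        state = rng_state
    else:
        state = np.array([np.uint64(int(rng_state))], dtype=np.uint64)
    return sample_candidates_from_state(w, int(mtry), state)


def sample_candidates_from_state(w, mtry, state):
    return _kernels.sample_candidates(w, mtry, state)


def best_split(X_node, y_node, candidates, min_node_size: int, task: str):
    """Best (feature, threshold) over candidates, or None as the leaf signal."""
    if task not in TASKS:
        raise ParameterError(f"task must be one of {TASKS}")
    X = np.ascontiguousarray(X_node, dtype=np.float64)
    n = X.shape[0]
    if n < max(2, 2 * int(min_node_size)):
        return None
    cand = np.sort(np.asarray(list(candidates), dtype=np.int64))
    if task == "classification":
        y_codes, n_classes = _encode_labels(np.asarray(y_node))[0:2]
        yk = y_codes.astype(np.float64)
        task_code = _kernels.CLASSIFICATION
    else:
        yk = np.ascontiguousarray(y_node, dtype=np.float64)
        n_classes = 1
        task_code = _kernels.REGRESSION
    samples = np.arange(n, dtype=np.int64)
    f, thr, dec, _ = _kernels.best_split(X, yk, samples, 0, n, cand, task_code, n_classes)
    if f < 0 or dec <= 0.0:
        return None
    return SplitDecision(feature=int(f), threshold=float(thr), impurity_decrease=float(dec))


def _encode_labels(y):
    classes, codes = np.unique(y, return_inverse=True)
    return codes.astype(np.float64), len(classes), classes


def grow_tree(
    data: Dataset,
    weights=None,
    mtry=None,
    min_node_size=None,
    tree_seed: int = 0,
    task: str = "regression",
    bootstrap: bool = True,
) -> Tree:
    """Grow one tree: bootstrap of m samples, weighted candidates per node."""
    if data.n_samples == 0 or data.n_features == 0:
        raise DataError("cannot grow a tree on an empty Dataset")
    if data.y is None:
        raise DataError("Dataset has no target vector y")
    w = _check_weights(weights, data.n_features)
    mtry = resolve_mtry(mtry, data.n_features)
    min_node_size = resolve_min_node_size(min_node_size, task)
    X = np.ascontiguousarray(data.X, dtype=np.float64)
    if task == "classification":
        yk, n_classes, _ = _encode_labels(data.y)
        task_code = _kernels.CLASSIFICATION
    else:
        yk = np.ascontiguousarray(data.y, dtype=np.float64)
        n_classes = 1
        task_code = _kernels.REGRESSION
    arrays = _kernels.grow_tree(
        X, yk, w, mtry, min_node_size, task_code, n_classes,
        np.uint64(int(tree_seed) % 2**64), 1 if bootstrap else 0,
    )
    return Tree(*arrays)


def plan_subforests(
    n_trees: int, n_workers: int, master_seed: int
) -> List[Tuple[int, int]]:
    """Per-tree seeds, pure functions of (master_seed, tree_index).

    The plan is identical for every worker count; workers only decide how the
    list is chunked (contiguously) at growth time.
    """
    if int(n_trees) < 1:
        raise ParameterError(f"n_trees must be >= 1, got {n_trees}")
    if int(n_workers) < 1:
        raise ParameterError(f"n_workers must be >= 1, got {n_workers}")
    return [(t, _seeds.tree_seed(master_seed, t)) for t in range(int(n_trees))]


def _chunk_bounds(n_trees: int, n_workers: int) -> List[Tuple[int, int]]:
    n_workers = min(n_workers, n_trees)
    base, extra = divmod(n_trees, n_workers)
    bounds, start = [], 0
    for k in range(n_workers):
        size = base + (1 if k < extra else 0)
        bounds.append((start, start + size))
        start += size
    return bounds


def grow_forest(
    data: Dataset,
    weights=None,
    n_trees: int = 100,
    mtry=None,
    min_node_size=None,
    master_seed: int = 0,
    n_workers: int = 1,
    task: str = "regression",
    bootstrap: bool = True,
) -> Forest:
    """Grow ``n_trees`` trees from the sub-forest plan and concatenate them."""
    if task not in TASKS:
        raise ParameterError(f"task must be one of {TASKS}")
    if data.y is None:
        raise DataError("Dataset has no target vector y")
    w = _check_weights(weights, data.n_features)
    mtry_r = resolve_mtry(mtry, data.n_features)
    mns = resolve_min_node_size(min_node_size, task)
    plan = plan_subforests(n_trees, n_workers, master_seed)

    X = np.ascontiguousarray(data.X, dtype=np.float64)
    classes = None
    if task == "classification":
        yk, n_classes, classes = _encode_labels(data.y)
        task_code = _kernels.CLASSIFICATION
    else:
        yk = np.ascontiguousarray(data.y, dtype=np.float64)
        n_classes = 1
        task_code = _kernels.REGRESSION
    boot = 1 if bootstrap else 0

    def _grow_chunk(chunk):
        return [
            Tree(*_kernels.grow_tree(
                X, yk, w, mtry_r, mns, task_code, n_classes,
                np.uint64(seed), boot,
            ))
            for _, seed in chunk
        ]

    if n_workers == 1 or n_trees == 1:
        trees = _grow_chunk(plan)
    else:
        bounds = _chunk_bounds(n_trees, n_workers)
        # numba kernels release the GIL, so threads give real parallelism
        # while keeping every tree's RNG stream private and deterministic
        chunks = Parallel(n_jobs=len(bounds), prefer="threads")(
            delayed(_grow_chunk)(plan[a:b]) for a, b in bounds
        )
        trees = [t for chunk in chunks for t in chunk]

    return Forest(
        trees=trees,
        task=task,
        mtry=mtry_r,
        min_node_size=mns,
        master_seed=int(master_seed),
        feature_ids=list(data.feature_ids),
        classes=classes,
    )


def impurity_importance(forest: Forest) -> np.ndarray:
    """Per-feature impurity decrease summed over all splits, / n_trees."""
    if forest.n_trees == 0:
        raise ParameterError("forest has no trees")
    imp = np.zeros(forest.n_features, np.float64)
    for tree in forest.trees:
        internal = tree.feature >= 0
        np.add.at(imp, tree.feature[internal], tree.decrease[internal])
    return imp / forest.n_trees


def predict(forest: Forest, X_new) -> np.ndarray:
    """Mean of tree predictions (regression) or majority vote (classification)."""
    X = np.ascontiguousarray(X_new, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != forest.n_features:
        raise DataError(
            f"X has {X.shape[1] if X.ndim == 2 else '?'} columns, "
            f"forest was trained on {forest.n_features} features"
        )
    n = X.shape[0]
    if forest.task == "regression":
        acc = np.zeros(n, np.float64)
        for tree in forest.trees:
            acc += tree.predict(X)
        return acc / forest.n_trees
    n_classes = len(forest.classes)
    votes = np.zeros((n, n_classes), np.int64)
    for tree in forest.trees:
        codes = tree.predict(X).astype(np.int64)
        votes[np.arange(n), codes] += 1
    return forest.classes[np.argmax(votes, axis=1)]  # argmax ties -> lowest code


# ---------------------------------------------------------------------------
# estimators


class _BaseWeightedForest(BaseEstimator):
    _task = None

    def __init__(
        self,
        n_trees=100,
        mtry="sqrt",
        min_node_size=None,
        n_workers=1,
        random_state=0,
        bootstrap=True,
    ):
        self.n_trees = n_trees
        self.mtry = mtry
        self.min_node_size = min_node_size
        self.n_workers = n_workers
        self.random_state = random_state
        self.bootstrap = bootstrap

    def fit(self, X, y, feature_weights=None):
        data = self._as_dataset(X, y)
        self.forest_ = grow_forest(
            data,
            weights=feature_weights,
            n_trees=self.n_trees,
            mtry=self.mtry,
            min_node_size=self.min_node_size,
            master_seed=0 if self.random_state is None else int(self.random_state),
            n_workers=self.n_workers,
            task=self._task,
            bootstrap=self.bootstrap,
        )
        self.n_features_in_ = data.n_features
        self.feature_names_in_ = np.asarray(data.feature_ids, dtype=object)
        self.feature_importances_ = impurity_importance(self.forest_)
        if self.forest_.classes is not None:
            self.classes_ = self.forest_.classes
        return self

    def predict(self, X):
        if not hasattr(self, "forest_"):
            raise ParameterError("estimator is not fitted; call fit first")
        X = self._as_matrix(X)
        return predict(self.forest_, X)

    @staticmethod
    def _as_matrix(X):
        if hasattr(X, "to_numpy"):
            return X.to_numpy(dtype=np.float64)
        return np.asarray(X, dtype=np.float64)

    def _as_dataset(self, X, y):
        if isinstance(X, Dataset):
            return Dataset(X.X, y=np.asarray(y), feature_ids=X.feature_ids,
                           sample_ids=X.sample_ids)
        feature_ids = None
        if hasattr(X, "columns"):
            feature_ids = [str(c) for c in X.columns]
        return Dataset(self._as_matrix(X), y=np.asarray(y), feature_ids=feature_ids)


class WeightedRandomForestRegressor(RegressorMixin, _BaseWeightedForest):
    """Random-forest regressor with weighted candidate-feature sampling.

    Parameters
    ----------
    n_trees : int, default 100
        Ensemble size.
    mtry : int or "sqrt", default "sqrt"
        Candidate features drawn (from the weighted distribution) per node;
        ``"sqrt"`` resolves to floor(sqrt(n_features)).
    min_node_size : int or None
        Nodes with fewer than ``2 * min_node_size`` samples become leaves;
        None resolves to 5 for regression.
    n_workers : int, default 1
        Thread count for sub-forest growth; never affects results.
    random_state : int, default 0
        Master seed; the forest is a pure function of (data, weights,
        parameters, master seed).
    """

    _task = "regression"


class WeightedRandomForestClassifier(ClassifierMixin, _BaseWeightedForest):
    """Random-forest classifier with weighted candidate-feature sampling.

    Gini impurity drives splits; leaves predict the majority class.  See
    `WeightedRandomForestRegressor` for parameters (``min_node_size`` defaults
    to 1 for classification).
    """

    _task = "classification"
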