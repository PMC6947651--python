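"""Iterative Random Forest: forests boosted by importance reweighting.

One iteration = grow a weighted-sampling forest, take its impurity
importance, sum-normalize it, and use it as the feature-sampling weights of
the next forest.  Iteration 1 uses uniform weights, so a single iteration is
exactly a plain random forest.  Because the weights are raw normalized
importance with no floor, a feature whose importance hits zero is never
sampled again — weight zero is absorbing, and later iterations concentrate on
a shrinking feature set.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin

from . import _seeds
from .dataset import Dataset
from .exceptions import ParameterError
from .forest import (
    Forest,
    _BaseWeightedForest,
    grow_forest,
    impurity_importance,
)

logger = logging.getLogger(__name__)


@dataclass
class IRFConfig:
    """Parameters of an iterative run (see `run_irf`)."""

    n_iterations: int = 5
    n_trees: int = 100
    mtry: object = "sqrt"
    min_node_size: Optional[int] = None
    master_seed: int = 0
    weights_path: Optional[str] = None
    n_workers: int = 1
    task: str = "regression"

    def __post_init__(self):
        if int(self.n_iterations) < 1:
            raise ParameterError(f"n_iterations must be >= 1, got {self.n_iterations}")
        if int(self.n_trees) < 1:
            raise ParameterError(f"n_trees must be >= 1, got {self.n_trees}")


@dataclass
class IRFResult:
    per_iteration_importance: List[np.ndarray]
    final_importance: np.ndarray
    final_forest: Forest

    @property
    def n_iterations(self) -> int:
        return len(self.per_iteration_importance)


def normalize_importance(v) -> np.ndarray:
    """Importance scores -> sampling weights summing to 1.

    All-zero vectors fall back to uniform weights (with a warning) so the
    next forest can still be grown.
    """
    v = np.asarray(v, dtype=np.float64)
    if (v < 0).any():
        raise ParameterError("importance scores must be nonnegative")
    total = v.sum()
    if total <= 0:
        warnings.warn(
            "all importance scores are zero; falling back to uniform weights",
            stacklevel=2,
        )
        return np.full(v.size, 1.0 / v.size)
    return v / total


def run_irf(data: Dataset, config: IRFConfig) -> IRFResult:
    """Run ``config.n_iterations`` reweighted forests on ``data``.

    When ``config.weights_path`` is set, the weights are written to that file
    after each iteration and re-read before the next (full ``%.17g``
    precision, so the round trip is value-exact).
    """
    from . import io  # local import: io depends on dataset only

    weights = np.ones(data.n_features, np.float64)
    per_iteration: List[np.ndarray] = []
    forest = None
    for k in range(config.n_iterations):
        seed_k = _seeds.iteration_seed(config.master_seed, k)
        forest = grow_forest(
            data,
            weights=weights,
            n_trees=config.n_trees,
            mtry=config.mtry,
            min_node_size=config.min_node_size,
            master_seed=seed_k,
            n_workers=config.n_workers,
            task=config.task,
        )
        importance = impurity_importance(forest)
        per_iteration.append(importance)
        if k + 1 < config.n_iterations:
            weights = normalize_importance(importance)
            if config.weights_path is not None:
                io.write_weights(data.feature_ids, weights, config.weights_path)
                weights = io.read_weights(config.weights_path, data.feature_ids)
        elif config.weights_path is not None:
            io.write_weights(
                data.feature_ids, normalize_importance(importance), config.weights_path
            )
    return IRFResult(
        per_iteration_importance=per_iteration,
        final_importance=per_iteration[-1],
        final_forest=forest,
    )


def recommend_tree_count(n_features: int, mtry: int, coverage: float = 0.95) -> int:
    """Trees needed so each feature has a ``coverage`` chance of being among
    the candidates in the first two layers (3 decision nodes) of some tree.

    Under uniform sampling, a feature is drawn into a node's candidate set
    with probability mtry/p; over ``3 T`` nodes the number of inclusions is
    modeled as Poisson with rate ``3 T mtry / p``, giving
    ``T = ceil(-ln(1 - coverage) * p / (3 mtry))``.  When ``mtry == p`` every
    feature is certainly considered at the root, so one tree suffices.
    """
    n_features, mtry = int(n_features), int(mtry)
    if not (0.0 < coverage < 1.0):
        raise ParameterError(f"coverage must be in (0, 1), got {coverage}")
    if not (1 <= mtry <= n_features):
        raise ParameterError(
            f"mtry must be in [1, n_features], got {mtry} with p={n_features}"
        )
    if mtry == n_features:
        return 1
    return int(math.ceil(-math.log(1.0 - coverage) * n_features / (3.0 * mtry)))


class _BaseIterativeForest(_BaseWeightedForest):
    def __init__(
        self,
        n_iterations=5,
        n_trees=100,
        mtry="sqrt",
        min_node_size=None,
        n_workers=1,
        random_state=0,
        weights_path=None,
    ):
        self.n_iterations = n_iterations
        self.n_trees = n_trees
        self.mtry = mtry
        self.min_node_size = min_node_size
        self.n_workers = n_workers
        self.random_state = random_state
        self.weights_path = weights_path

    def fit(self, X, y, feature_weights=None):
        if feature_weights is not None:
            raise ParameterError(
                "iterative forests derive their own weights; "
                "pass feature_weights to WeightedRandomForest* instead"
            )
        data = self._as_dataset(X, y)
        config = IRFConfig(
            n_iterations=self.n_iterations,
            n_trees=self.n_trees,
            mtry=self.mtry,
            min_node_size=self.min_node_size,
            master_seed=0 if self.random_state is None else int(self.random_state),
            weights_path=self.weights_path,
            n_workers=self.n_workers,
            task=self._task,
        )
        result = run_irf(data, config)
        self.n_features_in_ = data.n_features
        self.feature_names_in_ = np.asarray(data.feature_ids, dtype=object)
        self.per_iteration_importances_ = result.per_iteration_importance
        self.feature_importances_ = result.final_importance
        self.forest_ = result.final_forest
        if self.forest_.classes is not None:
            self.classes_ = self.forest_.classes
        return self


class IterativeRandomForestRegressor(RegressorMixin, _BaseIterativeForest):
    """Iterative Random Forest for a continuous target.

    Fitted attributes: ``per_iteration_importances_`` (one vector per
    iteration), ``feature_importances_`` (last iteration), ``forest_``
    (last-iteration ensemble, used by ``predict``).
    """

    _task = "regression"


class IterativeRandomForestClassifier(ClassifierMixin, _BaseIterativeForest):
    """Iterative Random Forest for a categorical target."""

    _task = "classification"
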