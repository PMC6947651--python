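"""iRF-LOOP: leave-one-out prediction networks.

For each of the n features (genes), run one iterative random forest with that
feature as the target and the remaining n−1 as predictors.  Each run's final
importance vector becomes one column of an n × n matrix; the diagonal (a
gene's importance for predicting itself) is zero by construction, and every
column is normalized by its sum.  The result reads as a directed adjacency
matrix — entry (A, B) is the weight of edge A→B, gene A's importance for
predicting gene B — a Predictive Expression Network when the inputs are
expression profiles.  The matrix is generally asymmetric.

Per-target seeds are keyed by a stable hash of the target's gene id, and
predictors are canonically ordered inside each run, so the network is
invariant (up to conjugate permutation) under any reordering of the input
genes, and the n runs can be scheduled in any order.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, List, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import _seeds
from .dataset import Dataset
from .exceptions import ParameterError
from .irf import IRFConfig, run_irf

EDGE_COLUMNS = ["source", "target", "weight"]


def irf_loop(data: Dataset, config: IRFConfig) -> pd.DataFrame:
    """Leave-one-out importance matrix, diagonal-zeroed and column-normalized.

    Returns a genes × genes DataFrame: column j holds the (normalized)
    importances of every other gene for predicting gene j.  A constant target
    column yields an all-zero column with a warning.
    """
    if data.n_features < 2:
        raise ParameterError("iRF-LOOP needs at least 2 features")
    gene_ids = list(data.feature_ids)
    order = sorted(range(len(gene_ids)), key=lambda k: gene_ids[k])
    canonical = Dataset(
        X=data.X[:, order],
        feature_ids=[gene_ids[k] for k in order],
        sample_ids=list(data.sample_ids),
    )
    raw = pd.DataFrame(0.0, index=gene_ids, columns=gene_ids)
    for gene in canonical.feature_ids:
        predictors, y = canonical.drop_feature(gene)
        if np.ptp(y) == 0:
            warnings.warn(
                f"target {gene!r} is constant; its column is all-zero",
                stacklevel=2,
            )
            continue
        sub = IRFConfig(
            n_iterations=config.n_iterations,
            n_trees=config.n_trees,
            mtry=config.mtry,
            min_node_size=config.min_node_size,
            master_seed=_seeds.target_seed(config.master_seed, gene),
            n_workers=config.n_workers,
            task="regression",
        )
        predictors = Dataset(
            predictors.X, y=y,
            feature_ids=predictors.feature_ids,
            sample_ids=predictors.sample_ids,
        )
        result = run_irf(predictors, sub)
        raw.loc[predictors.feature_ids, gene] = result.final_importance
    return normalize_columns(raw)


def normalize_columns(raw) -> pd.DataFrame:
    """Divide each positive-sum column by its sum; all-zero columns stay zero."""
    if isinstance(raw, pd.DataFrame):
        values = raw.to_numpy(dtype=np.float64, copy=True)
        index, columns = raw.index, raw.columns
    else:
        values = np.array(raw, dtype=np.float64, copy=True)
        index = columns = pd.RangeIndex(values.shape[0])
    if (values < 0).any():
        raise ParameterError("adjacency entries must be nonnegative")
    sums = values.sum(axis=0)
    positive = sums > 0
    values[:, positive] /= sums[positive]
    return pd.DataFrame(values, index=index, columns=columns)


def threshold_edges(adj: pd.DataFrame, top_fraction: float) -> pd.DataFrame:
    """Keep the top ``top_fraction`` of the strictly positive edge scores.

    The cutoff is the ceil(top_fraction * |Z|)-th largest positive entry of
    the pooled matrix Z (zeros removed first); ties at the cutoff are all
    kept, so nested fractions give nested edge lists.  Output columns are
    (source, target, weight), sorted by descending weight then ids.
    """
    if not (0.0 < top_fraction <= 1.0):
        raise ParameterError(f"top_fraction must be in (0, 1], got {top_fraction}")
    values = adj.to_numpy(dtype=np.float64)
    rows, cols = np.nonzero(values > 0)
    if rows.size == 0:
        warnings.warn("adjacency matrix has no positive entries", stacklevel=2)
        return pd.DataFrame(columns=EDGE_COLUMNS)
    weights = values[rows, cols]
    k = int(math.ceil(top_fraction * weights.size))
    cutoff = np.partition(weights, weights.size - k)[weights.size - k]
    keep = weights >= cutoff
    frame = pd.DataFrame(
        {
            "source": np.asarray(adj.index, dtype=object)[rows[keep]],
            "target": np.asarray(adj.columns, dtype=object)[cols[keep]],
            "weight": weights[keep],
        }
    )
    frame = frame.sort_values(
        ["weight", "source", "target"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return frame


class IRFLoop(BaseEstimator):
    """Leave-one-out network inference as an estimator.

    ``fit(X)`` takes a samples × genes matrix (DataFrame column names become
    gene ids) and exposes the normalized directed network as ``adjacency_``;
    ``edge_list(top_fraction)`` thresholds it into a directed edge list.

    Parameters mirror the per-target iterative forests: ``n_iterations``,
    ``n_trees``, ``mtry``, ``min_node_size``, ``n_workers``, ``random_state``.
    """

    def __init__(
        self,
        n_iterations=3,
        n_trees=300,
        mtry="sqrt",
        min_node_size=None,
        n_workers=1,
        random_state=0,
    ):
        self.n_iterations = n_iterations
        self.n_trees = n_trees
        self.mtry = mtry
        self.min_node_size = min_node_size
        self.n_workers = n_workers
        self.random_state = random_state

    def fit(self, X, y=None):
        if isinstance(X, Dataset):
            data = X
        elif hasattr(X, "columns"):
            data = Dataset.from_frame(X)
        else:
            data = Dataset(np.asarray(X, dtype=np.float64))
        config = IRFConfig(
            n_iterations=self.n_iterations,
            n_trees=self.n_trees,
            mtry=self.mtry,
            min_node_size=self.min_node_size,
            master_seed=0 if self.random_state is None else int(self.random_state),
            n_workers=self.n_workers,
            task="regression",
        )
        self.adjacency_ = irf_loop(data, config)
        self.gene_ids_ = list(self.adjacency_.columns)
        self.n_features_in_ = len(self.gene_ids_)
        return self

    def edge_list(self, top_fraction: float = 1.0) -> pd.DataFrame:
        if not hasattr(self, "adjacency_"):
            raise ParameterError("estimator is not fitted; call fit first")
        return threshold_edges(self.adjacency_, top_fraction)
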