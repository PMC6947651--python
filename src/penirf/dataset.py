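"""The in-memory sample × feature container shared by all forest code."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import DataError


@dataclass
class Dataset:
    """A samples × features matrix with ids, plus an optional target.

    Parameters
    ----------
    X : ndarray, shape (n_samples, n_features)
        Real-valued predictors; NaN is rejected.
    y : ndarray of shape (n_samples,), optional
        Regression target (floats) or class labels (any hashable values).
    feature_ids, sample_ids : sequences of str
        Unique identifiers; generated as ``f0..`` / ``s0..`` when omitted.
    """

    X: np.ndarray
    y: Optional[np.ndarray] = None
    feature_ids: Sequence[str] = field(default=None)
    sample_ids: Sequence[str] = field(default=None)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2:
            raise DataError(f"X must be 2-D, got shape {self.X.shape}")
        m, p = self.X.shape
        if np.isnan(self.X).any():
            raise DataError("X contains NaN values")
        if self.y is not None:
            self.y = np.asarray(self.y)
            if self.y.shape != (m,):
                raise DataError(
                    f"y has length {self.y.shape}, expected ({m},) to match X rows"
                )
            if self.y.dtype.kind == "f" and np.isnan(self.y.astype(float)).any():
                raise DataError("y contains NaN values")
        if self.feature_ids is None:
            self.feature_ids = [f"f{j}" for j in range(p)]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if len(self.feature_ids) != p:
            raise DataError("feature_ids length does not match X columns")
        if len(set(self.feature_ids)) != p:
            dup = _first_duplicate(self.feature_ids)
            raise DataError(f"duplicate feature id: {dup!r}")
        if self.sample_ids is None:
            self.sample_ids = [f"s{i}" for i in range(m)]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sample_ids) != m:
            raise DataError("sample_ids length does not match X rows")
        if len(set(self.sample_ids)) != m:
            dup = _first_duplicate(self.sample_ids)
            raise DataError(f"duplicate sample id: {dup!r}")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, y=None) -> "Dataset":
        """Build from a samples × features DataFrame (index = sample ids)."""
        return cls(
            X=frame.to_numpy(dtype=np.float64),
            y=None if y is None else np.asarray(y),
            feature_ids=[str(c) for c in frame.columns],
            sample_ids=[str(i) for i in frame.index],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=self.sample_ids, columns=self.feature_ids)

    def drop_feature(self, feature_id: str) -> tuple["Dataset", np.ndarray]:
        """Split one feature out as a target: returns (rest, that column)."""
        j = self.feature_ids.index(feature_id)
        keep = [k for k in range(self.n_features) if k != j]
        rest = Dataset(
            X=self.X[:, keep],
            feature_ids=[self.feature_ids[k] for k in keep],
            sample_ids=list(self.sample_ids),
        )
        return rest, self.X[:, j].copy()


def _first_duplicate(ids):
    seen = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None
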