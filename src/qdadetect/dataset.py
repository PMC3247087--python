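"""Labelled expression dataset container.

The package works on plain numeric matrices: ``n`` samples in rows,
``p`` features in columns, with a binary ``{0, 1}`` outcome per sample.
:class:`LabeledDataset` bundles the matrix with its feature identifiers
and, for simulated data, the bookkeeping of which columns carry the
planted bivariate signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


@dataclass
class LabeledDataset:
    """A samples x features matrix with binary class labels.

    Parameters
    ----------
    X : ndarray of shape (n_samples, n_features)
        Numeric data matrix; must be finite (no NaN/inf).
    y : ndarray of shape (n_samples,)
        Binary class labels in ``{0, 1}``.
    feature_ids : list of str
        Unique identifier per column.
    signal_columns : list of int, optional
        Column indices known to carry a planted signal.  Pure
        simulation bookkeeping — never used by the detector itself.
    """

    X: np.ndarray
    y: np.ndarray
    feature_ids: list[str]
    signal_columns: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ValueError(f"X must be 2-D, got shape {self.X.shape}")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains missing or non-finite values")
        if self.y.shape != (self.X.shape[0],):
            raise ValueError(
                f"label vector length {self.y.shape} does not match "
                f"{self.X.shape[0]} rows of X"
            )
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("labels must be binary {0, 1}")
        self.feature_ids = [str(f) for f in self.feature_ids]
        if len(self.feature_ids) != self.X.shape[1]:
            raise ValueError(
                f"{len(self.feature_ids)} feature ids for "
                f"{self.X.shape[1]} columns"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("feature_ids must be unique")
        self.signal_columns = [int(c) for c in self.signal_columns]
        for c in self.signal_columns:
            if not 0 <= c < self.X.shape[1]:
                raise ValueError(f"signal column {c} out of range")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def class_counts(self) -> tuple[int, int]:
        return int(np.sum(self.y == 0)), int(np.sum(self.y == 1))

    def select_features(self, columns: Sequence[int]) -> "LabeledDataset":
        """Return a new dataset restricted to ``columns`` (in the given order).

        ``signal_columns`` are remapped to the new indexing; planted
        columns that are dropped disappear from the bookkeeping.
        """
        columns = [int(c) for c in columns]
        remap = {old: new for new, old in enumerate(columns)}
        return LabeledDataset(
            X=self.X[:, columns],
            y=self.y.copy(),
            feature_ids=[self.feature_ids[c] for c in columns],
            signal_columns=[remap[c] for c in self.signal_columns if c in remap],
        )

    def select_samples(self, rows: Sequence[int]) -> "LabeledDataset":
        rows = [int(r) for r in rows]
        return LabeledDataset(
            X=self.X[rows],
            y=self.y[rows],
            feature_ids=list(self.feature_ids),
            signal_columns=list(self.signal_columns),
        )
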