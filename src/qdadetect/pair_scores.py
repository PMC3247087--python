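"""Comparison indexes for bivariate interaction screening.

Two published pair statistics serve as reference points for the
QDA-based detector:

* **TSP (top scoring pair)** — the absolute between-class difference in
  the probability that one feature's value lies below the other's,

      TSP = | P(x_i < x_j | y = 0) - P(x_i < x_j | y = 1) |,

  estimated by within-class empirical fractions.  Rank-based, hence
  invariant to any strictly increasing transform applied jointly to
  both features.  Ties ``x_i == x_j`` contribute 1/2 (midrank
  convention).

* **CorScor** (gap/substitution form) — the absolute change of the
  within-class Pearson correlation between classes,

      CorScor = | r_0(x_i, x_j) - r_1(x_i, x_j) |,

  bounded by 2 and invariant to separate positive-slope affine
  rescalings of the two features.

Both are symmetric in the class labels.  They capture order-switch and
correlation-change patterns specifically; the QDA detector is the
wider-purpose tool that also finds patterns (XOR, circular) these
indexes miss.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import LabeledDataset

__all__ = ["tsp_score", "corscor_score", "score_pairs"]


def _check_pair(xi, xj, y):
    xi = np.asarray(xi, float).ravel()
    xj = np.asarray(xj, float).ravel()
    y = np.asarray(y, int).ravel()
    if not (len(xi) == len(xj) == len(y)):
        raise ValueError("xi, xj and y must have equal lengths")
    if not ((y == 0).any() and (y == 1).any()):
        raise ValueError("both classes must be present")
    return xi, xj, y


def tsp_score(xi: np.ndarray, xj: np.ndarray, y: np.ndarray) -> float:
    """Top-scoring-pair statistic in [0, 1]."""
    xi, xj, y = _check_pair(xi, xj, y)
    fracs = []
    for c in (0, 1):
        a, b = xi[y == c], xj[y == c]
        fracs.append(np.mean((a < b) + 0.5 * (a == b)))
    return float(abs(fracs[0] - fracs[1]))


def corscor_score(xi: np.ndarray, xj: np.ndarray, y: np.ndarray) -> float:
    """Gap/substitution CorScor: |r_0 - r_1| in [0, 2]."""
    xi, xj, y = _check_pair(xi, xj, y)
    rs = []
    for c in (0, 1):
        a, b = xi[y == c], xj[y == c]
        for name, v in (("xi", a), ("xj", b)):
            if np.var(v) == 0.0:
                raise ValueError(
                    f"feature {name} has zero variance within class {c}; "
                    "the within-class correlation is undefined"
                )
        rs.append(np.corrcoef(a, b)[0, 1])
    return float(abs(rs[0] - rs[1]))


def score_pairs(
    data: LabeledDataset, pairs: Sequence[tuple[int, int]]
) -> pd.DataFrame:
    """TSP and CorScor for each (column_i, column_j) pair.

    Returns a frame with feature ids and both scores, one row per pair.
    """
    rows = []
    for i, j in pairs:
        xi, xj = data.X[:, int(i)], data.X[:, int(j)]
        rows.append(
            {
                "feature_i": data.feature_ids[int(i)],
                "feature_j": data.feature_ids[int(j)],
                "tsp": tsp_score(xi, xj, data.y),
                "corscor": corscor_score(xi, xj, data.y),
            }
        )
    return pd.DataFrame(rows, columns=["feature_i", "feature_j", "tsp", "corscor"])
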