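"""Reading, writing and preprocessing expression matrices.

Matrices travel as delimited text: samples in rows with a header line
of feature identifiers (the package's native layout), or features in
rows with the first column holding feature identifiers (the common
microarray export layout, transposed on load).  Labels are a
single-column file of 0/1 values.

Note on sample numbering: user-facing sample exclusion lists are
**1-based** (case 1 is the first row), matching how microarray case
numbers are quoted in practice; everything internal is 0-based.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import LabeledDataset

__all__ = [
    "read_expression",
    "write_expression",
    "preprocess_expression",
]


def _sep_for(path: str, delimiter: str | None) -> str:
    if delimiter:
        return delimiter
    ext = os.path.splitext(path)[1].lower()
    return "\t" if ext in (".tsv", ".tab", ".txt") else ","


def read_expression(
    matrix_path: str,
    labels_path: str,
    orientation: str = "samples-in-rows",
    delimiter: str | None = None,
) -> LabeledDataset:
    """Load a labelled expression matrix from delimited text.

    ``orientation='samples-in-rows'`` expects a header of feature ids
    and one sample per row; ``'features-in-rows'`` expects feature ids
    in the first column and transposes.  The delimiter is inferred from
    the extension (``.tsv``/``.tab``/``.txt`` -> tab, else comma)
    unless given explicitly.
    """
    if orientation not in ("samples-in-rows", "features-in-rows"):
        raise ValueError(
            "orientation must be 'samples-in-rows' or 'features-in-rows'"
        )
    sep = _sep_for(matrix_path, delimiter)
    # round_trip parsing keeps write -> read bit-identical
    if orientation == "samples-in-rows":
        frame = pd.read_csv(matrix_path, sep=sep, float_precision="round_trip")
    else:
        frame = pd.read_csv(
            matrix_path, sep=sep, index_col=0, float_precision="round_trip"
        ).T
    feature_ids = [str(c) for c in frame.columns]
    try:
        X = frame.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {matrix_path}: {exc}") from exc

    labels = pd.read_csv(labels_path, header=None).iloc[:, 0]
    try:
        y = labels.astype(int).to_numpy()
    except ValueError as exc:
        raise ValueError(f"non-numeric label in {labels_path}: {exc}") from exc
    if not np.isin(y, (0, 1)).all():
        bad = sorted(set(y) - {0, 1})
        raise ValueError(f"labels in {labels_path} must be 0/1; found {bad}")
    if len(y) != X.shape[0]:
        raise ValueError(
            f"{matrix_path} has {X.shape[0]} samples but {labels_path} "
            f"has {len(y)} labels"
        )
    return LabeledDataset(X=X, y=y, feature_ids=feature_ids)


def write_expression(
    data: LabeledDataset,
    matrix_path: str,
    labels_path: str | None = None,
    delimiter: str | None = None,
) -> None:
    """Write the matrix (samples in rows, feature-id header) and labels."""
    sep = _sep_for(matrix_path, delimiter)
    pd.DataFrame(data.X, columns=data.feature_ids).to_csv(
        matrix_path, sep=sep, index=False
    )
    if labels_path is not None:
        pd.Series(data.y).to_csv(labels_path, index=False, header=False)


def preprocess_expression(
    data: LabeledDataset,
    log_transform: bool = False,
    standardize: bool = False,
    sample_exclusions: Sequence[int] = (),
) -> LabeledDataset:
    """Outlier removal, log transform and per-feature standardization.

    ``sample_exclusions`` are 1-based case numbers, removed before any
    statistic is computed.  ``log_transform`` applies the natural log
    (all values must be positive); ``standardize`` centres and scales
    each feature to mean 0, SD 1.
    """
    n = data.n_samples
    excl = set()
    for case in sample_exclusions:
        case = int(case)
        if not 1 <= case <= n:
            raise ValueError(f"sample exclusion {case} outside 1..{n}")
        excl.add(case - 1)
    keep = [i for i in range(n) if i not in excl]
    out = data.select_samples(keep)
    X = out.X
    if log_transform:
        if np.any(X <= 0):
            r, c = np.argwhere(X <= 0)[0]
            raise ValueError(
                f"log transform needs positive values; sample {r + 1}, "
                f"feature {out.feature_ids[c]!r} is {X[r, c]:g}"
            )
        X = np.log(X)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            raise ValueError(
                f"feature {out.feature_ids[zero[0]]!r} has zero variance; "
                "cannot standardize"
            )
        X = (X - X.mean(axis=0)) / sd
    return LabeledDataset(
        X=X,
        y=out.y,
        feature_ids=list(out.feature_ids),
        signal_columns=list(out.signal_columns),
    )
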