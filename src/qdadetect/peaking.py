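"""Peaking-phenomenon benchmark: error-vs-dimension curves and the
signal-versus-noise overlap experiment.

The peaking phenomenon is the degradation of a designed classifier as
uninformative features are added at fixed sample size.  Two study
designs quantify it here:

* :func:`peaking_curve` — mean CV error of a classifier as a planted
  two-column signal is padded with ``p - 2`` standard-normal noise
  columns, over a grid of dimensions ``p``.

* :func:`overlap_experiment` — at each ``p``, B replicate datasets with
  the signal and B pure-noise datasets are scored by QDA CV error.  The
  separation between the two error populations is summarised by the
  standardised mean difference (the univariate Mahalanobis distance)

      Delta = |mean_signal - mean_noise| / s_pooled

  and reported as the Gaussian overlap ``Phi(-Delta / 2)`` — the error
  rate of the linear discriminant between two equal-variance Gaussians
  at that separation.  Small overlap means the classifier can still
  tell a feature chunk that hides a signal from one that is pure noise.

Replicate ``b`` of both arms uses root seed ``seed + b``, so the arms
are paired and the whole experiment is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np
from scipy.stats import norm

from .dataset import LabeledDataset
from .qda import cv_error, fit_qda, qda_predict, stratified_folds, PriorSpec
from .scenarios import ScenarioSpec, add_noise_features, simulate_noise_only, simulate_scenario

__all__ = [
    "ClassifierAdapter",
    "QDAAdapter",
    "adapter_cv_error",
    "PeakingConfig",
    "OverlapResult",
    "pooled_delta",
    "overlap_from_delta",
    "overlap_between",
    "peaking_curve",
    "overlap_experiment",
]


class ClassifierAdapter(Protocol):
    """Call contract for plugging external classifiers into the bench."""

    def fit(self, X: np.ndarray, y: np.ndarray) -> None: ...

    def error(self, X: np.ndarray, y: np.ndarray) -> float: ...


class QDAAdapter:
    """The internal plug-in QDA exposed through the adapter contract."""

    def __init__(self, priors: PriorSpec = "empirical", ridge: float | None = None):
        self.priors = priors
        self.ridge = ridge
        self._model = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> None:
        self._model = fit_qda(X, y, priors=self.priors, ridge=self.ridge)

    def error(self, X: np.ndarray, y: np.ndarray) -> float:
        if self._model is None:
            raise RuntimeError("adapter not fitted")
        return float(np.mean(qda_predict(self._model, X) != np.asarray(y)))


def adapter_cv_error(
    adapter_factory: Callable[[], ClassifierAdapter],
    X: np.ndarray,
    y: np.ndarray,
    k: int = 10,
    seed: int = 0,
) -> float:
    """Pooled stratified k-fold CV error for any adapter-contract classifier.

    Uses the same fold assignment as :func:`qdadetect.qda.cv_error`, so
    the QDA adapter reproduces that estimate exactly.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    folds = stratified_folds(y, k, seed)
    wrong = 0
    for f in range(k):
        test = folds == f
        adapter = adapter_factory()
        adapter.fit(X[~test], y[~test])
        wrong += adapter.error(X[test], y[test]) * test.sum()
    return float(wrong / len(y))


@dataclass
class PeakingConfig:
    """Study design for the peaking and overlap experiments.

    ``scenario=None`` runs a noise-only design (no planted signal) with
    class sizes ``n0``/``n1``.
    """

    scenario: ScenarioSpec | None
    p_grid: Sequence[int] = (2, 5, 10, 15, 20, 30)
    B: int = 100
    k: int = 10
    seed: int = 0
    n0: int = 40
    n1: int = 40
    classifier: Callable[[], ClassifierAdapter] | None = None

    def __post_init__(self) -> None:
        self.p_grid = [int(p) for p in self.p_grid]
        if not self.p_grid or min(self.p_grid) < 2:
            raise ValueError("p_grid entries must be >= 2")
        if sorted(self.p_grid) != self.p_grid:
            raise ValueError("p_grid must be increasing")
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.scenario is not None:
            self.n0 = self.scenario.n0
            self.n1 = self.scenario.n1


@dataclass
class OverlapResult:
    """Signal vs noise error populations at one dimension."""

    p: int
    errors_signal: np.ndarray
    errors_noise: np.ndarray
    delta: float
    overlap: float


def pooled_delta(a: np.ndarray, b: np.ndarray) -> float:
    """Standardised mean difference with the pooled standard deviation.

    Two identical samples give 0; a zero pooled SD with unequal means is
    an error (the separation is then infinite/undefined).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per population")
    gap = abs(a.mean() - b.mean())
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
        a.size + b.size - 2
    )
    if sp2 == 0.0:
        if gap == 0.0:
            return 0.0
        raise ValueError(
            "zero pooled variance with unequal means: separation undefined"
        )
    return float(gap / np.sqrt(sp2))


def overlap_from_delta(delta: float) -> float:
    """Gaussian overlap Phi(-Delta/2); 0.5 iff the populations coincide."""
    if delta < 0:
        raise ValueError("delta must be non-negative")
    return float(norm.cdf(-delta / 2.0))


def overlap_between(a: np.ndarray, b: np.ndarray) -> float:
    return overlap_from_delta(pooled_delta(a, b))


def _replicate_error(
    config: PeakingConfig, p: int, rep_seed: int, noise_only: bool
) -> float:
    if noise_only:
        data: LabeledDataset = simulate_noise_only(
            config.n0, config.n1, p, seed=rep_seed
        )
    else:
        assert config.scenario is not None
        data = simulate_scenario(config.scenario.with_seed(rep_seed))
        if p > 2:
            data = add_noise_features(data, p - 2, seed=rep_seed)
    if config.classifier is None:
        return cv_error(data.X, data.y, k=config.k, seed=rep_seed).error_rate
    return adapter_cv_error(
        config.classifier, data.X, data.y, k=config.k, seed=rep_seed
    )


def peaking_curve(config: PeakingConfig) -> list[tuple[int, float]]:
    """Mean CV error at each dimension of the grid.

    For each ``p`` the planted two-column pattern (or pure noise when
    ``config.scenario is None``) is padded to ``p`` columns and scored
    by the classifier's k-fold CV error, averaged over B replicates.
    """
    noise_only = config.scenario is None
    curve = []
    for p in config.p_grid:
        errs = [
            _replicate_error(config, p, config.seed + b, noise_only)
            for b in range(config.B)
        ]
        curve.append((p, float(np.mean(errs))))
    return curve


def overlap_experiment(config: PeakingConfig) -> list[OverlapResult]:
    """Signal-vs-noise error-population overlap at each dimension.

    Requires a planted scenario and ``B >= 2`` (a variance is needed).
    """
    if config.scenario is None:
        raise ValueError("overlap_experiment needs a planted scenario")
    if config.B < 2:
        raise ValueError("need B >= 2 replicates to estimate a variance")
    results = []
    for p in config.p_grid:
        sig = np.array(
            [
                _replicate_error(config, p, config.seed + b, noise_only=False)
                for b in range(config.B)
            ]
        )
        noi = np.array(
            [
                _replicate_error(config, p, config.seed + b, noise_only=True)
                for b in range(config.B)
            ]
        )
        delta = pooled_delta(sig, noi)
        results.append(
            OverlapResult(
                p=p,
                errors_signal=sig,
                errors_noise=noi,
                delta=delta,
                overlap=overlap_from_delta(delta),
            )
        )
    return results
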