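"""Binary quadratic discriminant analysis with plug-in estimates.

The classifier assumes two Gaussian class-conditional populations
``N(mu_0, Sigma_0)`` and ``N(mu_1, Sigma_1)`` with prior probabilities
``pi_0, pi_1``.  The discriminant score of a point ``x`` is the
log-posterior difference

    d(x) = log pi_1 - 1/2 log|Sigma_1| - 1/2 (x - mu_1)' Sigma_1^{-1} (x - mu_1)
         - log pi_0 + 1/2 log|Sigma_0| + 1/2 (x - mu_0)' Sigma_0^{-1} (x - mu_0)

whose zero level set is a hyperquadric; ``d(x) > 0`` predicts class 1
(ties at exactly zero break to class 0).  Plug-in fitting substitutes
class sample means and unbiased (``n_c - 1`` denominator) sample
covariances, plus a small ridge on the covariance diagonal so that
folds with fewer samples than features remain usable.

Error rates come from stratified k-fold cross-validation: within each
class, samples are shuffled by a seeded PCG64 stream and dealt
round-robin into folds, so per-class fold sizes differ by at most one
and the whole estimate is a deterministic function of
``(X, y, k, seed, priors, ridge)``.

:func:`cv_errors_for_subsets` is the throughput path used by the
blockwise search: class moments are computed once per fold on the full
feature space, and each column subset's QDA reduces to extracting
sub-vectors/sub-matrices of those moments.  Subset results are
numerically identical to running :func:`cv_error` on the corresponding
column slice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

__all__ = [
    "QDAModel",
    "CVErrorEstimate",
    "fit_qda",
    "qda_discriminant",
    "qda_predict",
    "stratified_folds",
    "cv_error",
    "cv_errors_for_subsets",
]

#: Relative ridge: ridge_c = RIDGE_REL * trace(Sigma_c) / p, per class.
RIDGE_REL = 1e-6

_SALT_FOLDS = 101

PriorSpec = Union[str, tuple[float, float]]


@dataclass
class QDAModel:
    """Fitted (or population) parameters of the quadratic rule."""

    mean0: np.ndarray
    mean1: np.ndarray
    cov0: np.ndarray
    cov1: np.ndarray
    prior0: float
    prior1: float
    ridge0: float = 0.0
    ridge1: float = 0.0

    def __post_init__(self) -> None:
        self.mean0 = np.asarray(self.mean0, float).ravel()
        self.mean1 = np.asarray(self.mean1, float).ravel()
        self.cov0 = np.atleast_2d(np.asarray(self.cov0, float))
        self.cov1 = np.atleast_2d(np.asarray(self.cov1, float))
        p = self.mean0.size
        if self.mean1.size != p or self.cov0.shape != (p, p) or self.cov1.shape != (p, p):
            raise ValueError("inconsistent parameter dimensions")
        if not (0 < self.prior0 < 1 and 0 < self.prior1 < 1):
            raise ValueError("priors must lie in (0, 1)")
        if abs(self.prior0 + self.prior1 - 1.0) > 1e-9:
            raise ValueError("priors must sum to 1")
        self._chol = []
        self._logdet = []
        for c, (cov, r) in enumerate(
            [(self.cov0, self.ridge0), (self.cov1, self.ridge1)]
        ):
            reg = cov + r * np.eye(p)
            try:
                L = np.linalg.cholesky(reg)
            except np.linalg.LinAlgError as exc:
                raise ValueError(
                    f"regularized covariance of class {c} is not positive "
                    f"definite (ridge={r:g}); increase the ridge"
                ) from exc
            self._chol.append(L)
            self._logdet.append(2.0 * np.log(np.diag(L)).sum())

    @property
    def n_features(self) -> int:
        return self.mean0.size


@dataclass
class CVErrorEstimate:
    """Pooled stratified k-fold misclassification rate."""

    error_rate: float
    k: int
    fold_errors: np.ndarray
    seed: int


def _resolve_priors(priors: PriorSpec, n0: int, n1: int) -> tuple[float, float]:
    if priors == "empirical":
        n = n0 + n1
        return n0 / n, n1 / n
    if priors == "balanced":
        return 0.5, 0.5
    try:
        p0, p1 = (float(priors[0]), float(priors[1]))
    except (TypeError, IndexError) as exc:
        raise ValueError(
            "priors must be 'empirical', 'balanced' or a (p0, p1) pair"
        ) from exc
    if not (0 < p0 < 1 and 0 < p1 < 1) or abs(p0 + p1 - 1.0) > 1e-9:
        raise ValueError("explicit priors must lie in (0, 1) and sum to 1")
    return p0, p1


def fit_qda(
    X: np.ndarray,
    y: np.ndarray,
    priors: PriorSpec = "empirical",
    ridge: float | None = None,
) -> QDAModel:
    """Plug-in QDA fit.

    ``ridge=None`` applies the default per-class ridge
    ``RIDGE_REL * trace(Sigma_c) / p``; an explicit non-negative scalar
    is used verbatim for both classes.
    """
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, int)
    n0, n1 = int(np.sum(y == 0)), int(np.sum(y == 1))
    if n0 < 2 or n1 < 2:
        raise ValueError(
            f"each class needs at least 2 samples to estimate a covariance "
            f"(got n0={n0}, n1={n1})"
        )
    p = X.shape[1]
    means, covs, ridges = [], [], []
    for c in (0, 1):
        Xc = X[y == c]
        means.append(Xc.mean(axis=0))
        cov = np.atleast_2d(np.cov(Xc, rowvar=False, ddof=1))
        covs.append(cov)
        ridges.append(
            float(ridge) if ridge is not None else RIDGE_REL * np.trace(cov) / p
        )
    p0, p1 = _resolve_priors(priors, n0, n1)
    return QDAModel(
        mean0=means[0],
        mean1=means[1],
        cov0=covs[0],
        cov1=covs[1],
        prior0=p0,
        prior1=p1,
        ridge0=ridges[0],
        ridge1=ridges[1],
    )


def _scores(model: QDAModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} features, got {X.shape[1]}"
        )
    from scipy.linalg import solve_triangular

    out = []
    for mu, L, logdet, prior in [
        (model.mean0, model._chol[0], model._logdet[0], model.prior0),
        (model.mean1, model._chol[1], model._logdet[1], model.prior1),
    ]:
        z = solve_triangular(L, (X - mu).T, lower=True)
        quad = np.einsum("ij,ij->j", z, z)
        out.append(np.log(prior) - 0.5 * logdet - 0.5 * quad)
    return out[1] - out[0]


def qda_discriminant(model: QDAModel, x: np.ndarray) -> float:
    """Quadratic discriminant score of a single point (sign -> class)."""
    return float(_scores(model, np.asarray(x, float)[None, :])[0])


def qda_predict(model: QDAModel, X: np.ndarray) -> np.ndarray:
    """Predicted labels; the tie at score exactly 0 breaks to class 0."""
    return (_scores(model, X) > 0).astype(int)


def stratified_folds(y: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Deterministic stratified fold assignment (values ``0..k-1``).

    Within each class the samples are shuffled by a seeded stream and
    dealt round-robin, so per-class fold sizes differ by at most one.
    """
    y = np.asarray(y, int)
    if k < 2:
        raise ValueError("need at least 2 folds")
    fold = np.empty(y.shape[0], dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        if len(idx) < k:
            raise ValueError(
                f"class {cls} has only {len(idx)} samples; use k <= {len(idx)}"
            )
        rng = np.random.default_rng([_SALT_FOLDS, cls, int(seed)])
        rng.shuffle(idx)
        fold[idx] = np.arange(len(idx)) % k
    return fold


def cv_errors_for_subsets(
    X: np.ndarray,
    y: np.ndarray,
    subsets: Sequence[Sequence[int]],
    k: int = 10,
    seed: int = 0,
    priors: PriorSpec = "empirical",
    ridge: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pooled k-fold QDA CV error for many column subsets at once.

    Shares one stratified fold assignment across all subsets (so
    rankings compare like with like) and evaluates every subset against
    per-fold class moments computed once on the full matrix.

    Returns ``(errors, miscounts, fold_sizes)`` where ``errors`` has one
    pooled error per subset, ``miscounts`` is ``(n_subsets, k)`` test
    misclassification counts and ``fold_sizes`` the test-fold sizes.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    n, p = X.shape
    subsets = [np.asarray(s, dtype=int) for s in subsets]
    for s in subsets:
        if s.size == 0 or s.min() < 0 or s.max() >= p:
            raise ValueError("subset indices out of range")
    folds = stratified_folds(y, k, seed)
    miscounts = np.zeros((len(subsets), k), dtype=int)
    fold_sizes = np.bincount(folds, minlength=k)

    # Group subsets of equal size for batched linear algebra.
    by_size: dict[int, list[int]] = {}
    for i, s in enumerate(subsets):
        by_size.setdefault(len(s), []).append(i)

    for f in range(k):
        test = folds == f
        train = ~test
        ytr = y[train]
        n_tr = np.array([np.sum(ytr == 0), np.sum(ytr == 1)])
        if n_tr.min() < 2:
            raise ValueError(
                f"fold {f} leaves a training class with fewer than 2 samples"
            )
        mus, covs = [], []
        for c in (0, 1):
            Xc = X[train & (y == c)]
            mus.append(Xc.mean(axis=0))
            covs.append(np.atleast_2d(np.cov(Xc, rowvar=False, ddof=1)))
        p0, p1 = _resolve_priors(priors, int(n_tr[0]), int(n_tr[1]))
        log_priors = (np.log(p0), np.log(p1))
        Xte = X[test]
        yte = y[test]

        for size, members in by_size.items():
            idx = np.stack([subsets[i] for i in members])  # (g, size)
            scores = []
            for c in (0, 1):
                sig = covs[c][idx[:, :, None], idx[:, None, :]]  # (g, s, s)
                if ridge is not None:
                    r = np.full(len(members), float(ridge))
                else:
                    r = RIDGE_REL * np.trace(sig, axis1=1, axis2=2) / size
                sig = sig + r[:, None, None] * np.eye(size)
                try:
                    L = np.linalg.cholesky(sig)
                except np.linalg.LinAlgError as exc:
                    raise ValueError(
                        f"a regularized class-{c} covariance is not positive "
                        f"definite in fold {f}; increase the ridge"
                    ) from exc
                logdet = 2.0 * np.log(
                    np.diagonal(L, axis1=1, axis2=2)
                ).sum(axis=1)
                delta = Xte[:, idx].transpose(1, 2, 0) - mus[c][idx][:, :, None]
                z = np.linalg.solve(L, delta)  # (g, s, n_test)
                quad = np.einsum("gsn,gsn->gn", z, z)
                scores.append(log_priors[c] - 0.5 * logdet[:, None] - 0.5 * quad)
            pred = (scores[1] - scores[0] > 0).astype(int)  # (g, n_test)
            miscounts[members, f] = (pred != yte[None, :]).sum(axis=1)

    errors = miscounts.sum(axis=1) / n
    return errors, miscounts, fold_sizes


def cv_error(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 10,
    seed: int = 0,
    priors: PriorSpec = "empirical",
    ridge: float | None = None,
) -> CVErrorEstimate:
    """Stratified k-fold CV misclassification rate of plug-in QDA.

    The pooled rate is total misclassified test samples divided by n.
    """
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    errors, miscounts, fold_sizes = cv_errors_for_subsets(
        X, y, [np.arange(X.shape[1])], k=k, seed=seed, priors=priors, ridge=ridge
    )
    return CVErrorEstimate(
        error_rate=float(errors[0]),
        k=k,
        fold_errors=miscounts[0] / fold_sizes,
        seed=int(seed),
    )
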