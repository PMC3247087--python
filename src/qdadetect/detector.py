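"""The QDA interaction detector: blockwise search for feature pairs
with weak marginal but strong bivariate class separation.

An exhaustive pairwise scan of ``p`` features needs ``p(p-1)/2`` QDA
fits (1,999,000 for p = 2000).  The detector instead partitions the
columns into blocks of ``bsize`` features and scores every unordered
pair of blocks by the 10-fold CV error of a QDA fitted on the union of
their columns — ``nb(nb-1)/2`` fits for ``nb = ceil(p / bsize)`` blocks
(79,800 for p = 2000, bsize = 5).  Because QDA stays resistant to
peaking up to roughly 10–15 features, requiring ``2 * bsize <= p_star``
guarantees a block-pair union never exceeds the safe dimension: a
matching hiding a bivariate signal scores a low error while pure-noise
matchings score near chance, so the sorted matchings form a useful
ranking.  A second stage rescans the few top-ranked matchings
exhaustively — every feature pair inside each union, plus univariate
errors on the diagonal — producing heat matrices whose "hot spots"
localise the interacting pair.

Everything is deterministic given the config seed: one stratified fold
assignment is shared by all fits, and all ties break lexicographically
on indices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .dataset import LabeledDataset
from .qda import PriorSpec, cv_errors_for_subsets

__all__ = [
    "BlockSearchConfig",
    "BlockMatchingRanking",
    "HeatMatrix",
    "PairResult",
    "partition_blocks",
    "count_fits",
    "rank_block_matchings",
    "pairwise_heatmatrix",
    "detect_interactions",
    "screen_by_importance",
    "drop_duplicate_features",
]


@dataclass
class BlockSearchConfig:
    """Tuning knobs of the blockwise search.

    ``p_star`` is the dimension up to which QDA is trusted to resist
    peaking; configs violating ``2 * bsize <= p_star`` are rejected so
    no block-pair union can exceed it.
    """

    bsize: int = 5
    p_star: int = 10
    k: int = 10
    seed: int = 0
    top_m: int = 6
    shuffle_features: bool = False
    priors: PriorSpec = "empirical"
    ridge: float | None = None

    def __post_init__(self) -> None:
        if self.bsize < 1:
            raise ValueError("bsize must be >= 1")
        if 2 * self.bsize > self.p_star:
            raise ValueError(
                f"2 * bsize = {2 * self.bsize} exceeds the peaking-resistance "
                f"threshold p_star = {self.p_star}; shrink bsize"
            )
        if self.top_m < 1:
            raise ValueError("top_m must be >= 1")
        if self.k < 2:
            raise ValueError("k must be >= 2")


class Matching(NamedTuple):
    block_a: int
    block_b: int
    cv_error: float


class PairResult(NamedTuple):
    feature_i: int
    feature_j: int
    cv_error: float
    source_rank: int


@dataclass
class BlockMatchingRanking:
    """Stage-1 output: every block pair sorted by its joint CV error."""

    blocks: list[np.ndarray]
    matchings: list[Matching]
    n_fits: int


@dataclass
class HeatMatrix:
    """Symmetric pairwise CV-error matrix over a feature subset.

    Off-diagonal entries are two-feature QDA CV errors, the diagonal
    holds univariate errors (exposing "not so weak" single components).
    """

    feature_subset: list[int]
    errors: np.ndarray

    @property
    def diagonal(self) -> np.ndarray:
        return np.diag(self.errors)


def partition_blocks(
    p: int, bsize: int, shuffle: bool = False, seed: int = 0
) -> list[np.ndarray]:
    """Split column indices into consecutive blocks of ``bsize``.

    The last block holds the remainder when ``bsize`` does not divide
    ``p``.  With ``shuffle=True`` the column order is permuted by a
    seeded stream first (a robustness check against order effects).
    """
    if p < 2:
        raise ValueError("need at least 2 features")
    if bsize < 1:
        raise ValueError("bsize must be >= 1")
    order = np.arange(p)
    if shuffle:
        np.random.default_rng([23, int(seed)]).shuffle(order)
    return [order[i : i + bsize] for i in range(0, p, bsize)]


def count_fits(p: int, bsize: int) -> tuple[int, int]:
    """(blockwise, exhaustive) fit counts for a p-feature search.

    Exhaustive pairwise search needs ``p(p-1)/2`` fits; the blockwise
    stage needs ``nb(nb-1)/2`` with ``nb = ceil(p / bsize)`` blocks.
    """
    if p < 2:
        raise ValueError("need at least 2 features")
    if bsize < 1:
        raise ValueError("bsize must be >= 1")
    nb = -(-p // bsize)
    return nb * (nb - 1) // 2, p * (p - 1) // 2


def rank_block_matchings(
    data: LabeledDataset, config: BlockSearchConfig
) -> BlockMatchingRanking:
    """Stage 1: score every unordered block pair by joint QDA CV error.

    All fits share the fold assignment derived from ``config.seed``;
    the result is sorted ascending by error with lexicographic
    tie-breaking on the block indices.
    """
    blocks = partition_blocks(
        data.n_features, config.bsize, config.shuffle_features, config.seed
    )
    pairs = [
        (a, b) for a in range(len(blocks)) for b in range(a + 1, len(blocks))
    ]
    if not pairs:
        raise ValueError(
            "only one block: increase p or decrease bsize so there is "
            "at least one block pair to score"
        )
    subsets = [np.concatenate([blocks[a], blocks[b]]) for a, b in pairs]
    errors, _, _ = cv_errors_for_subsets(
        data.X,
        data.y,
        subsets,
        k=config.k,
        seed=config.seed,
        priors=config.priors,
        ridge=config.ridge,
    )
    matchings = sorted(
        (Matching(a, b, float(e)) for (a, b), e in zip(pairs, errors)),
        key=lambda m: (m.cv_error, m.block_a, m.block_b),
    )
    return BlockMatchingRanking(blocks=blocks, matchings=matchings, n_fits=len(pairs))


def pairwise_heatmatrix(
    data: LabeledDataset,
    feature_subset: Sequence[int],
    config: BlockSearchConfig,
) -> HeatMatrix:
    """Stage 2: exhaustive pairwise QDA errors within a feature subset.

    Every unordered pair is scored by two-feature CV error; the
    diagonal carries the univariate errors.  Fold seeds match stage 1.
    """
    subset = [int(c) for c in feature_subset]
    if len(subset) < 2:
        raise ValueError("need at least 2 features in the subset")
    m = len(subset)
    subsets: list[list[int]] = [[c] for c in subset]
    pair_pos = []
    for i in range(m):
        for j in range(i + 1, m):
            pair_pos.append((i, j))
            subsets.append([subset[i], subset[j]])
    errors, _, _ = cv_errors_for_subsets(
        data.X,
        data.y,
        subsets,
        k=config.k,
        seed=config.seed,
        priors=config.priors,
        ridge=config.ridge,
    )
    mat = np.zeros((m, m))
    np.fill_diagonal(mat, errors[:m])
    for (i, j), e in zip(pair_pos, errors[m:]):
        mat[i, j] = mat[j, i] = e
    return HeatMatrix(feature_subset=subset, errors=mat)


def detect_interactions(
    data: LabeledDataset, config: BlockSearchConfig
) -> list[PairResult]:
    """Full two-stage pipeline: rank matchings, rescan the top ones.

    Takes the ``top_m`` best block matchings, scores all feature pairs
    inside each matching's union, pools the unique pairs and returns
    them sorted ascending by CV error (ties lexicographic on indices).
    ``source_rank`` records the best (1-based) matching rank in which a
    pair was scored.
    """
    ranking = rank_block_matchings(data, config)
    seen: dict[tuple[int, int], PairResult] = {}
    for rank, match in enumerate(ranking.matchings[: config.top_m], start=1):
        union = np.concatenate(
            [ranking.blocks[match.block_a], ranking.blocks[match.block_b]]
        )
        union = np.sort(union)
        heat = pairwise_heatmatrix(data, union, config)
        m = len(union)
        for a in range(m):
            for b in range(a + 1, m):
                key = (int(union[a]), int(union[b]))
                if key not in seen:
                    seen[key] = PairResult(
                        key[0], key[1], float(heat.errors[a, b]), rank
                    )
    return sorted(
        seen.values(), key=lambda r: (r.cv_error, r.feature_i, r.feature_j)
    )


def screen_by_importance(
    data: LabeledDataset,
    importance: Sequence[float],
    keep_rank_above: int,
) -> tuple[LabeledDataset, list[str]]:
    """Remove the ``keep_rank_above`` highest-importance features.

    Strong marginal features (e.g. the top of a random-forest
    mean-decrease-Gini ranking) are put aside before the search, which
    is designed for signals those filters reject.  The importance
    vector itself comes from the caller; ties break by column order.

    Returns the screened dataset and the removed feature ids.
    """
    importance = np.asarray(importance, float)
    if importance.shape != (data.n_features,):
        raise ValueError(
            f"importance length {importance.shape} does not match "
            f"{data.n_features} features"
        )
    if keep_rank_above >= data.n_features:
        raise ValueError("screening would remove every feature")
    if keep_rank_above < 0:
        raise ValueError("keep_rank_above must be non-negative")
    # stable sort on -importance: ties resolve to the earlier column
    order = np.argsort(-importance, kind="stable")
    removed = np.sort(order[:keep_rank_above])
    keep = np.setdiff1d(np.arange(data.n_features), removed)
    return (
        data.select_features(keep),
        [data.feature_ids[c] for c in removed],
    )


def drop_duplicate_features(data: LabeledDataset) -> LabeledDataset:
    """Drop columns exactly identical to an earlier column (first kept)."""
    seen: dict[bytes, int] = {}
    keep: list[int] = []
    for c in range(data.n_features):
        key = data.X[:, c].tobytes()
        if key not in seen:
            seen[key] = c
            keep.append(c)
    if len(keep) == data.n_features:
        return data
    return data.select_features(keep)
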