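"""Blockwise search: partitioning, fit counts, ranking and localisation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from qdadetect import (
    BlockSearchConfig,
    ScenarioSpec,
    add_noise_features,
    count_fits,
    cv_error,
    detect_interactions,
    drop_duplicate_features,
    pairwise_heatmatrix,
    partition_blocks,
    rank_block_matchings,
    screen_by_importance,
    simulate_noise_only,
    simulate_scenario,
)
from qdadetect.dataset import LabeledDataset


def _planted(scenario, p, seed):
    data = simulate_scenario(ScenarioSpec(scenario, seed=seed))
    return add_noise_features(data, p - 2, seed=seed)


class TestPartition:
    def test_block_counts(self):
        assert len(partition_blocks(2000, 5)) == 400
        assert len(partition_blocks(7, 7)) == 1

    def test_remainder_block(self):
        blocks = partition_blocks(23, 5)
        assert [len(b) for b in blocks] == [5, 5, 5, 5, 3]
        assert set(np.concatenate(blocks)) == set(range(23))

    def test_shuffle_is_seeded_and_still_partitions(self):
        a = partition_blocks(40, 5, shuffle=True, seed=1)
        b = partition_blocks(40, 5, shuffle=True, seed=1)
        c = partition_blocks(40, 5, shuffle=True, seed=2)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))
        assert not all(np.array_equal(x, y) for x, y in zip(a, c))
        assert sorted(np.concatenate(a)) == list(range(40))

    @given(p=st.integers(2, 300), bsize=st.integers(1, 30))
    def test_partition_is_disjoint_and_covering(self, p, bsize):
        blocks = partition_blocks(p, bsize)
        flat = np.concatenate(blocks)
        assert len(flat) == p and set(flat) == set(range(p))
        assert all(len(b) == bsize for b in blocks[:-1])


class TestCountFits:
    def test_reference_workloads(self):
        assert count_fits(2000, 5) == (79_800, 1_999_000)
        assert count_fits(2, 1) == (1, 1)

    def test_against_enumeration(self):
        blocks = partition_blocks(17, 4)
        enumerated = sum(1 for _ in itertools.combinations(range(len(blocks)), 2))
        assert count_fits(17, 4)[0] == enumerated
        assert count_fits(17, 4)[1] == sum(
            1 for _ in itertools.combinations(range(17), 2)
        )

    @given(p=st.integers(2, 500), bsize=st.integers(1, 40))
    def test_blockwise_never_exceeds_exhaustive(self, p, bsize):
        blockwise, exhaustive = count_fits(p, bsize)
        assert blockwise <= exhaustive
        assert (blockwise == exhaustive) == (bsize == 1)


class TestConfig:
    def test_peaking_protection_rule(self):
        with pytest.raises(ValueError, match="p_star"):
            BlockSearchConfig(bsize=6, p_star=10)
        BlockSearchConfig(bsize=5, p_star=10)  # boundary is allowed

    def test_basic_validation(self):
        with pytest.raises(ValueError):
            BlockSearchConfig(bsize=0)
        with pytest.raises(ValueError):
            BlockSearchConfig(top_m=0)


class TestRanking:
    def test_planted_block_rises_to_the_top(self):
        data = _planted("linear", 50, seed=2)
        ranking = rank_block_matchings(data, BlockSearchConfig(seed=2))
        top = ranking.matchings[0]
        assert 0 in (top.block_a, top.block_b)  # block 0 holds the signal
        assert ranking.n_fits == count_fits(50, 5)[0] == 45
        errors = [m.cv_error for m in ranking.matchings]
        assert errors == sorted(errors)
        # matchings of pure noise sit at the bottom with high error
        assert ranking.matchings[-1].cv_error > 0.35

    def test_all_noise_has_no_low_error_matching(self):
        data = simulate_noise_only(40, 40, 50, seed=0)
        ranking = rank_block_matchings(data, BlockSearchConfig(seed=0))
        assert ranking.matchings[0].cv_error > 0.25

    def test_deterministic_given_seed(self):
        data = _planted("circular", 30, seed=4)
        a = rank_block_matchings(data, BlockSearchConfig(seed=4))
        b = rank_block_matchings(data, BlockSearchConfig(seed=4))
        assert a.matchings == b.matchings


class TestHeatMatrix:
    def test_symmetry_range_and_single_pair(self):
        data = _planted("xor", 20, seed=6)
        config = BlockSearchConfig(seed=6)
        heat = pairwise_heatmatrix(data, range(10), config)
        np.testing.assert_array_equal(heat.errors, heat.errors.T)
        assert np.all((heat.errors >= 0) & (heat.errors <= 1))

        two = pairwise_heatmatrix(data, [0, 1], config)
        assert two.errors[0, 1] == cv_error(
            data.X[:, [0, 1]], data.y, k=10, seed=6
        ).error_rate

    def test_matches_bruteforce_recomputation(self):
        data = _planted("linear", 12, seed=8)
        config = BlockSearchConfig(seed=8)
        subset = [0, 1, 4, 7, 9]
        heat = pairwise_heatmatrix(data, subset, config)
        for a in range(len(subset)):
            for b in range(a, len(subset)):
                cols = [subset[a]] if a == b else [subset[a], subset[b]]
                ref = cv_error(data.X[:, cols], data.y, k=10, seed=8).error_rate
                assert heat.errors[a, b] == ref

    def test_planted_xor_pair_is_the_hot_spot(self):
        data = _planted("xor", 50, seed=3)
        config = BlockSearchConfig(seed=3)
        ranking = rank_block_matchings(data, config)
        top = ranking.matchings[0]
        union = np.sort(np.concatenate(
            [ranking.blocks[top.block_a], ranking.blocks[top.block_b]]
        ))
        heat = pairwise_heatmatrix(data, union, config)
        off = heat.errors + np.eye(len(union))  # mask diagonal
        i, j = np.unravel_index(np.argmin(off), off.shape)
        assert {int(union[i]), int(union[j])} == {0, 1}


class TestDetect:
    def test_single_matching_collapses_to_heatmatrix(self):
        data = _planted("linear", 10, seed=5)
        config = BlockSearchConfig(seed=5)
        pairs = detect_interactions(data, config)
        heat = pairwise_heatmatrix(data, range(10), config)
        assert len(pairs) == 45
        for r in pairs:
            a = heat.feature_subset.index(r.feature_i)
            b = heat.feature_subset.index(r.feature_j)
            assert r.cv_error == heat.errors[a, b]
        errs = [r.cv_error for r in pairs]
        assert errs == sorted(errs)

    def test_top_pair_is_global_minimum_of_rescanned_subsets(self):
        data = _planted("circular", 40, seed=7)
        config = BlockSearchConfig(seed=7, top_m=3)
        pairs = detect_interactions(data, config)
        ranking = rank_block_matchings(data, config)
        best = np.inf
        for match in ranking.matchings[:3]:
            union = np.sort(np.concatenate(
                [ranking.blocks[match.block_a], ranking.blocks[match.block_b]]
            ))
            heat = pairwise_heatmatrix(data, union, config)
            off = heat.errors + np.eye(len(union))
            best = min(best, off.min())
        assert pairs[0].cv_error == best

    @pytest.mark.parametrize("scenario", ["linear", "xor", "circular"])
    def test_recovers_planted_pair(self, scenario):
        hits = 0
        for seed in range(10):
            data = _planted(scenario, 50, seed=seed)
            pairs = detect_interactions(data, BlockSearchConfig(seed=seed))
            hits += (pairs[0].feature_i, pairs[0].feature_j) == (0, 1)
        assert hits >= 9


class TestScreening:
    def _dataset(self, rng, p=30):
        X = rng.normal(size=(12, p))
        y = np.repeat([0, 1], 6)
        ids = [f"g{i}" for i in range(p)]
        return LabeledDataset(X=X, y=y, feature_ids=ids, signal_columns=[3, 4])

    def test_removes_top_importances(self, rng):
        data = self._dataset(rng, p=2000)
        importance = rng.random(2000)
        screened, removed = screen_by_importance(data, importance, 100)
        assert screened.n_features == 1900
        assert len(removed) == 100
        order = np.argsort(-importance, kind="stable")
        expected = {data.feature_ids[c] for c in order[:100]}
        assert set(removed) == expected

    def test_identity_and_ties(self, rng):
        data = self._dataset(rng)
        screened, removed = screen_by_importance(data, np.zeros(30), 0)
        assert removed == [] and screened.n_features == 30
        # all-tied importances: removal follows column order
        _, removed = screen_by_importance(data, np.zeros(30), 3)
        assert removed == ["g0", "g1", "g2"]

    def test_cannot_remove_everything(self, rng):
        data = self._dataset(rng)
        with pytest.raises(ValueError, match="every feature"):
            screen_by_importance(data, np.zeros(30), 30)

    def test_signal_columns_remapped(self, rng):
        data = self._dataset(rng)
        imp = np.zeros(30)
        imp[[0, 1, 2]] = 1.0
        screened, _ = screen_by_importance(data, imp, 3)
        assert screened.signal_columns == [0, 1]  # old columns 3, 4


class TestDuplicates:
    def test_removes_later_copy_and_is_idempotent(self, rng):
        X = rng.normal(size=(8, 6))
        X[:, 5] = X[:, 2]
        data = LabeledDataset(
            X=X, y=np.repeat([0, 1], 4), feature_ids=list("abcdef")
        )
        out = drop_duplicate_features(data)
        assert out.feature_ids == list("abcde")
        np.testing.assert_array_equal(out.X[:, 2], X[:, 2])
        again = drop_duplicate_features(out)
        assert again.feature_ids == out.feature_ids
        np.testing.assert_array_equal(again.X, out.X)
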