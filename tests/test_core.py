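import numpy as np
import pytest

from dcgnet import (
    SharingMatrix,
    WalkParams,
    cluster_level,
    estimate_cluster_count,
    level_from_sharing,
    run_regulated_walk,
    sharing_matrix,
)
from dcgnet.matrices import SimilarityMatrix

from conftest import block_correlation, perfect_block_similarity


def segments_as_sets(record):
    return {frozenset(s) for s in record.segments}


class TestRegulatedWalk:
    def test_disconnected_blocks_exhausted_before_crossing(self):
        """Zero cross-similarity traps the walk until its block is removed."""
        sim = perfect_block_similarity([2, 2])
        for seed in range(60):
            record = run_regulated_walk(sim, WalkParams(), seed=seed)
            assert segments_as_sets(record) == {frozenset({0, 1}), frozenset({2, 3})}

    def test_single_uniform_block_is_one_segment(self):
        sim = perfect_block_similarity([3])
        for seed in range(60):
            record = run_regulated_walk(sim, WalkParams(), seed=seed)
            assert segments_as_sets(record) == {frozenset({0, 1, 2})}

    def test_every_node_removed_exactly_once(self):
        sim = perfect_block_similarity([4, 3, 2])
        record = run_regulated_walk(sim, WalkParams(), seed=5)
        assert sorted(record.removal_order.tolist()) == list(range(9))
        assert np.all(np.diff(record.removal_steps) > 0)

    def test_planted_three_blocks_recovered_in_most_walks(self):
        """Monte-Carlo: segment majorities match planted blocks in >=90% of walks."""
        n_per = 5
        values = np.full((15, 15), 0.01)
        labels = np.repeat([0, 1, 2], n_per)
        for b in range(3):
            idx = np.flatnonzero(labels == b)
            values[np.ix_(idx, idx)] = 0.9
        np.fill_diagonal(values, 1.0)
        sim = SimilarityMatrix(values=values, temperature=1.0)
        good = 0
        for seed in range(200):
            record = run_regulated_walk(sim, WalkParams(removal_visits=3), seed=seed)
            majority = set()
            for seg in record.segments:
                counts = np.bincount(labels[list(seg)], minlength=3)
                majority.add(int(np.argmax(counts)))
            good += majority == {0, 1, 2}
        # a single walk is a noisy draw (the ensemble sharpens it); with
        # cross-similarity 0.01 the walk occasionally escapes a block early,
        # so block-covering majorities appear in most but not all walks
        assert good >= 160

    def test_too_few_nodes_rejected(self):
        sim = SimilarityMatrix(values=np.eye(1), temperature=1.0)
        with pytest.raises(ValueError, match="2 nodes"):
            run_regulated_walk(sim, WalkParams(), seed=0)


class TestSharingMatrix:
    def test_disconnected_blocks_give_zero_one_sharing(self):
        p = sharing_matrix(perfect_block_similarity([2, 2]), WalkParams(n_walks=30))
        expected = np.zeros((4, 4))
        expected[:2, :2] = 1.0
        expected[2:, 2:] = 1.0
        assert np.array_equal(p.values, expected)

    def test_single_walk_gives_indicator_entries(self):
        p = sharing_matrix(perfect_block_similarity([3, 2]), WalkParams(n_walks=1, seed=3))
        assert set(np.unique(p.values)) <= {0.0, 1.0}

    def test_within_exceeds_cross_sharing_on_planted_blocks(self):
        values = np.full((12, 12), 0.01)
        labels = np.repeat([0, 1, 2], 4)
        for b in range(3):
            idx = np.flatnonzero(labels == b)
            values[np.ix_(idx, idx)] = 0.9
        np.fill_diagonal(values, 1.0)
        sim = SimilarityMatrix(values=values, temperature=1.0)
        p = sharing_matrix(sim, WalkParams(n_walks=100, seed=7)).values
        within = labels[:, None] == labels[None, :]
        off = ~np.eye(12, dtype=bool)
        assert p[within & off].mean() - p[~within].mean() >= 0.5

    def test_reproducible_bit_for_bit(self):
        sim = perfect_block_similarity([3, 3])
        params = WalkParams(n_walks=20, seed=11)
        a = sharing_matrix(sim, params)
        b = sharing_matrix(sim, params)
        assert np.array_equal(a.values, b.values)

    def test_exchangeable_under_relabeling(self):
        """Permuting nodes permutes sharing, up to Monte-Carlo tolerance."""
        rng = np.random.default_rng(0)
        values = np.full((9, 9), 0.05)
        labels = np.repeat([0, 1, 2], 3)
        for b in range(3):
            idx = np.flatnonzero(labels == b)
            values[np.ix_(idx, idx)] = 0.85
        np.fill_diagonal(values, 1.0)
        perm = rng.permutation(9)
        sim = SimilarityMatrix(values=values, temperature=1.0)
        sim_p = SimilarityMatrix(values=values[np.ix_(perm, perm)], temperature=1.0)
        p = sharing_matrix(sim, WalkParams(n_walks=400, seed=1)).values
        p_perm = sharing_matrix(sim_p, WalkParams(n_walks=400, seed=2)).values
        assert np.abs(p[np.ix_(perm, perm)] - p_perm).max() < 0.15


class TestClusterCount:
    @pytest.mark.parametrize("n_blocks", range(1, 7))
    def test_block_diagonal_counts_exact(self, n_blocks):
        """Eigengap count equals block count for every composition with n <= 30."""
        rng = np.random.default_rng(n_blocks)
        for _ in range(10):
            sizes = rng.integers(2, 6, size=n_blocks)
            if sizes.sum() > 30:
                continue
            p = perfect_block_similarity(sizes.tolist()).values
            sharing = SharingMatrix(values=p, temperature=1.0, n_walks=1)
            assert estimate_cluster_count(sharing) == n_blocks

    def test_identity_counts_every_node(self):
        sharing = SharingMatrix(values=np.eye(5), temperature=1.0, n_walks=1)
        assert estimate_cluster_count(sharing) == 5

    def test_all_ones_is_one_cluster(self):
        sharing = SharingMatrix(values=np.ones((6, 6)), temperature=1.0, n_walks=1)
        assert estimate_cluster_count(sharing) == 1

    def test_asymmetric_rejected(self):
        bad = np.eye(3)
        bad[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            estimate_cluster_count(bad)


class TestClusterLevel:
    def test_disconnected_blocks_recovered_exactly(self):
        corr = block_correlation([3, 3], within=1.0, between=0.0)
        level = cluster_level(corr, temperature=1.0, params=WalkParams(seed=2))
        assert level.k == 2
        assert len(set(level.membership[:3])) == 1
        assert len(set(level.membership[3:])) == 1
        assert level.membership[0] != level.membership[3]

    def test_all_equal_correlation_large_t_single_cluster(self):
        corr = block_correlation([6], within=0.9, between=0.9)
        level = cluster_level(corr, temperature=10.0, params=WalkParams(seed=2))
        assert level.k == 1

    def test_membership_labels_canonical(self):
        corr = block_correlation([3, 3, 3], within=1.0, between=0.0)
        level = cluster_level(corr, temperature=1.0, params=WalkParams(seed=4))
        assert sorted(set(level.membership)) == list(range(1, level.k + 1))
        assert level.membership[0] == 1  # first node always labelled 1


def test_level_from_sharing_respects_requested_k():
    p = perfect_block_similarity([3, 3, 3]).values
    sharing = SharingMatrix(values=p, temperature=1.0, n_walks=1)
    assert level_from_sharing(sharing, k=3).k == 3
    assert level_from_sharing(sharing, k=1).k == 1
    assert level_from_sharing(sharing, k=9).k == 9
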