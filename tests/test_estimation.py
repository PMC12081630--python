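import numpy as np
import pytest

from seedcap._errors import ConfigurationError
from seedcap.estimation import (
    ReducedData,
    back_reconstruct,
    cluster_frames,
    consensus_cluster,
    derive_caps,
    finalize_caps,
    pac_score,
    pool_frames,
    reduce_pca,
)

from oracles import pac_bruteforce


def _reduced_from_scores(scores):
    """Wrap raw coordinates as ReducedData (identity eigenbasis)."""
    scores = np.asarray(scores, dtype=float)
    d = scores.shape[1]
    return ReducedData(
        scores=scores,
        eigenvectors=np.eye(d),
        mean_map=np.zeros(d),
        explained_variance_fraction=1.0,
    )


class TestPCA:
    def test_exact_rank_identity(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(40, 3)) @ rng.normal(size=(3, 25))
        red = reduce_pca(x, variance_target=1.0)
        assert red.n_components == 3
        assert np.abs(back_reconstruct(red, red.scores) - x).max() < 1e-8

    def test_round_trip_at_full_variance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(30, 20))
        red = reduce_pca(x, variance_target=1.0)
        assert np.abs(back_reconstruct(red, red.scores) - x).max() < 1e-8

    def test_components_orthonormal(self):
        rng = np.random.default_rng(2)
        red = reduce_pca(rng.normal(size=(50, 12)), variance_target=0.95)
        g = red.eigenvectors.T @ red.eigenvectors
        assert np.allclose(g, np.eye(red.n_components), atol=1e-10)

    def test_isotropic_spectrum_keeps_about_90_components(self):
        rng = np.random.default_rng(3)
        red = reduce_pca(rng.normal(size=(4000, 100)), variance_target=0.90)
        assert 84 <= red.n_components <= 94

    def test_invalid_target_rejected(self):
        with pytest.raises(ConfigurationError):
            reduce_pca(np.zeros((5, 5)), variance_target=1.5)


class TestPAC:
    def test_perfectly_stable_matrix(self):
        rng = np.random.default_rng(4)
        m = (rng.random((12, 12)) > 0.5).astype(float)
        m = np.triu(m, 1)
        m = m + m.T + np.eye(12)
        assert pac_score(m) == 0.0

    def test_maximally_ambiguous_matrix(self):
        m = np.full((10, 10), 0.5)
        np.fill_diagonal(m, 1.0)
        assert pac_score(m) == 1.0

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            n = int(rng.integers(4, 30))
            m = rng.random((n, n))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 1.0)
            valid = rng.random((n, n)) > 0.1
            valid = valid | valid.T
            assert pac_score(m, valid=valid) == pytest.approx(
                pac_bruteforce(m, valid=valid), abs=1e-12
            )


class TestConsensus:
    def test_planted_k_recovery_on_blobs(self):
        """Four well-separated spherical blobs: stability peaks at K = 4."""
        rng = np.random.default_rng(6)
        centers = 10.0 * np.eye(4)  # equidistant, separation 10x within-SD
        x = np.vstack([c + rng.normal(size=(50, 4)) for c in centers])
        res = consensus_cluster(_reduced_from_scores(x), n_iter=50, rng_seed=6)
        assert res.chosen_k == 4
        assert res.pac[4] < min(res.pac[2], res.pac[3])

    def test_reproducible_under_fixed_seed(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(60, 4))
        red = _reduced_from_scores(x)
        a = consensus_cluster(red, k_range=[2, 3], n_iter=15, rng_seed=1)
        b = consensus_cluster(red, k_range=[2, 3], n_iter=15, rng_seed=1)
        for k in (2, 3):
            assert np.array_equal(a.consensus[k], b.consensus[k])
        assert a.pac == b.pac

    def test_consensus_matrix_properties(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(40, 3))
        res = consensus_cluster(_reduced_from_scores(x), k_range=[3], n_iter=20, rng_seed=2)
        m = res.consensus[3]
        assert np.allclose(m, m.T)
        assert np.all(np.diag(m) == 1.0)
        assert m.min() >= 0.0 and m.max() <= 1.0
        assert 0.0 <= res.pac[3] <= 1.0

    def test_too_small_subsample_rejected(self):
        with pytest.raises(ConfigurationError):
            consensus_cluster(
                _reduced_from_scores(np.zeros((6, 2))), k_range=[8], subsample_fraction=0.8
            )


class TestClusterFrames:
    def test_two_frames_two_clusters(self):
        red = _reduced_from_scores([[0.0, 0.0], [5.0, 5.0]])
        labels, centroids = cluster_frames(red, 2, rng_seed=0)
        assert sorted(labels.tolist()) == [1, 2]
        assert np.allclose(np.sort(centroids, axis=0), [[0, 0], [5, 5]])

    def test_duplicates_share_labels(self):
        rng = np.random.default_rng(9)
        base = rng.normal(scale=5.0, size=(3, 4))
        x = np.repeat(base, 10, axis=0)
        labels, _ = cluster_frames(_reduced_from_scores(x), 3, rng_seed=0)
        for i in range(3):
            block = labels[i * 10 : (i + 1) * 10]
            assert len(set(block.tolist())) == 1

    def test_labels_ordered_by_descending_size(self):
        rng = np.random.default_rng(10)
        x = np.vstack(
            [
                rng.normal(loc=0, scale=0.1, size=(30, 2)),
                rng.normal(loc=10, scale=0.1, size=(20, 2)),
                rng.normal(loc=-10, scale=0.1, size=(10, 2)),
            ]
        )
        labels, _ = cluster_frames(_reduced_from_scores(x), 3, rng_seed=0)
        sizes = [np.sum(labels == c) for c in (1, 2, 3)]
        assert sizes == [30, 20, 10]

    def test_recovers_planted_states(self, small_cfg, small_design, small_frame_sets):
        """Frame labels reach ARI >= 0.9 against the planted state sequence."""
        from sklearn.metrics import adjusted_rand_score

        fsets = [t[0] for t in small_frame_sets]
        truths = [t[2] for t in small_frame_sets]
        frames, _ = pool_frames(fsets)
        red = reduce_pca(frames)
        labels, _ = cluster_frames(red, small_cfg.n_states, rng_seed=0)
        true = np.concatenate(
            [tr.state_sequence[fs.frame_index] for fs, tr in zip(fsets, truths)]
        )
        assert adjusted_rand_score(true, labels) >= 0.9


class TestBackReconstruct:
    def test_zero_centroid_returns_mean(self):
        rng = np.random.default_rng(11)
        red = reduce_pca(rng.normal(size=(20, 10)), variance_target=0.9)
        rec = back_reconstruct(red, np.zeros(red.n_components))
        assert np.allclose(rec[0], red.mean_map, atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        red = reduce_pca(np.random.default_rng(12).normal(size=(20, 10)), 0.9)
        with pytest.raises(ConfigurationError):
            back_reconstruct(red, np.zeros(red.n_components + 1))

    def test_planted_pattern_recovery(self, small_cfg, small_design, small_frame_sets):
        """Back-reconstructed cluster maps correlate >= 0.9 with the planted
        patterns over non-seed voxels (optimal pairing)."""
        from scipy.optimize import linear_sum_assignment

        fsets = [t[0] for t in small_frame_sets]
        frames, _ = pool_frames(fsets)
        red = reduce_pca(frames)
        labels, centroids = cluster_frames(red, small_cfg.n_states, rng_seed=0)
        maps = back_reconstruct(red, centroids)
        scope = np.setdiff1d(np.arange(small_cfg.n_voxels), small_design.seed_voxel_ids)
        corr = np.corrcoef(maps[:, scope], small_design.state_patterns[:, scope])[
            : small_cfg.n_states, small_cfg.n_states :
        ]
        r, c = linear_sum_assignment(-corr)
        assert np.all(corr[r, c] >= 0.9)

    def test_true_state_centroids_survive_reduction(self, small_cfg, small_frame_sets):
        """Projecting each planted state's empirical centroid through the
        retained components and back reproduces it almost exactly: the
        0.90-variance cut discards noise, not state structure."""
        fsets = [t[0] for t in small_frame_sets]
        truths = [t[2] for t in small_frame_sets]
        frames, _ = pool_frames(fsets)
        red = reduce_pca(frames)
        true = np.concatenate(
            [tr.state_sequence[fs.frame_index] for fs, tr in zip(fsets, truths)]
        )
        for s in range(small_cfg.n_states):
            centroid = frames[true == s].mean(axis=0)
            score = (centroid - red.mean_map) @ red.eigenvectors
            rec = back_reconstruct(red, score)[0]
            assert np.corrcoef(rec, centroid)[0, 1] >= 0.95


class TestFinalizeCaps:
    def test_symmetric_map_balanced_tails(self):
        rng = np.random.default_rng(13)
        v = rng.normal(size=5000)
        m = np.concatenate([v, -v])  # exactly symmetric values
        caps = finalize_caps(m[None, :], np.ones(10, dtype=int))
        assert len(caps.pos_voxels[0]) == len(caps.neg_voxels[0])

    def test_tail_fraction_matches_normal(self):
        """|z| >= 1.04 keeps ~14.9% of voxels per tail under normality."""
        rng = np.random.default_rng(14)
        m = rng.normal(size=10_000)
        caps = finalize_caps(m[None, :], np.ones(5, dtype=int))
        assert len(caps.pos_voxels[0]) / 10_000 == pytest.approx(0.15, abs=0.01)
        assert len(caps.neg_voxels[0]) / 10_000 == pytest.approx(0.15, abs=0.01)

    def test_seed_voxels_removed_and_sets_disjoint(self):
        rng = np.random.default_rng(15)
        m = rng.normal(size=(2, 500))
        seed = np.arange(0, 50)
        caps = finalize_caps(m, np.array([1, 2]), seed_voxel_ids=seed)
        for c in range(2):
            assert np.intersect1d(caps.pos_voxels[c], seed).size == 0
            assert np.intersect1d(caps.neg_voxels[c], seed).size == 0
            assert np.intersect1d(caps.pos_voxels[c], caps.neg_voxels[c]).size == 0

    def test_occupancy_degenerate_and_conserved(self):
        m = np.random.default_rng(16).normal(size=(3, 100))
        caps = finalize_caps(m, np.ones(20, dtype=int))
        assert caps.occupancy_pct.tolist() == [100.0, 0.0, 0.0]
        mixed = finalize_caps(m, np.array([1, 1, 2, 3, 3, 3]))
        assert mixed.occupancy_pct.sum() == pytest.approx(100.0, abs=1e-6)

    def test_maps_are_zscored(self):
        m = np.random.default_rng(17).normal(loc=5, scale=3, size=(2, 400))
        caps = finalize_caps(m, np.array([1, 2]))
        assert np.allclose(caps.maps.mean(axis=1), 0.0, atol=1e-10)
        assert np.allclose(caps.maps.std(axis=1), 1.0, atol=1e-10)


class TestDeriveCaps:
    def test_end_to_end_with_fixed_k(self, small_cfg, small_design, small_frame_sets):
        fsets = [t[0] for t in small_frame_sets]
        d = derive_caps(
            fsets, k=4, rng_seed=0, seed_voxel_ids=small_design.seed_voxel_ids
        )
        assert d.cap_set.k == 4
        assert d.cap_set.occupancy_pct.sum() == pytest.approx(100.0, abs=1e-6)
        assert d.consensus is None
        assert d.cap_set.assignments.size == d.pooled_frames.shape[0]
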