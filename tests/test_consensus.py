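import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import latentdomains as ld
from latentdomains.consensus import ConsensusMatrix


def matrix_from_upper(upper, K=2):
    """Build a ConsensusMatrix for 3+ variables from given upper-tri indices."""
    m = len(upper)
    # solve p(p-1)/2 = m
    p = int((1 + np.sqrt(1 + 8 * m)) / 2)
    M = np.eye(p)
    iu = np.triu_indices(p, 1)
    M[iu] = upper
    M[(iu[1], iu[0])] = upper
    return ConsensusMatrix(
        indices=M, co_sample_counts=np.full((p, p), 10.0), K=K, n_iterations=10, fraction=0.8
    )


class TestConsensusCluster:
    def test_separable_blocks(self, planted_3block):
        _, table, truth = planted_3block
        M = ld.consensus_cluster(table.values.to_numpy(), K=3, n_iter=200, seed=0)
        blocks = truth.cluster_labels
        same = blocks[:, None] == blocks[None, :]
        off = ~np.eye(30, dtype=bool)
        assert M.indices[same & off].min() > 0.99
        assert M.indices[~same].max() < 0.01

    def test_symmetry_and_unit_diagonal(self, planted_3block):
        _, table, _ = planted_3block
        M = ld.consensus_cluster(table.values.to_numpy(), K=2, n_iter=20, seed=1)
        assert np.allclose(M.indices, M.indices.T)
        assert np.allclose(np.diag(M.indices), 1.0)
        assert M.indices.min() >= 0 and M.indices.max() <= 1

    def test_index_is_together_over_cosampled(self, planted_3block):
        _, table, _ = planted_3block
        M = ld.consensus_cluster(table.values.to_numpy(), K=3, n_iter=50, seed=2)
        # co-sampling counts must be near n_iter * fraction^2 on average
        iu = np.triu_indices(30, 1)
        assert abs(M.co_sample_counts[iu].mean() - 50 * 0.64) < 5

    def test_invalid_parameters_rejected(self):
        X = np.random.default_rng(0).standard_normal((50, 6))
        with pytest.raises(ValueError):
            ld.consensus_cluster(X, K=1)
        with pytest.raises(ValueError):
            ld.consensus_cluster(X, K=2, fraction=0.0)


class TestCdfAuc:
    def test_half_zero_half_one_gives_half(self):
        d = ld.consensus_cdf_auc(matrix_from_upper([0, 0, 0, 1, 1, 1]))
        assert d.auc == pytest.approx(0.5)

    def test_degenerate_distribution_single_step(self):
        d = ld.consensus_cdf_auc(matrix_from_upper([0.4, 0.4, 0.4]))
        assert d.cdf.shape == (1, 2)
        assert d.cdf[0, 0] == pytest.approx(0.4)
        assert d.cdf[0, 1] == pytest.approx(1.0)

    @given(st.lists(st.floats(0, 1), min_size=3, max_size=15))
    @settings(max_examples=30, deadline=None)
    def test_auc_always_in_unit_interval(self, vals):
        m = len(vals)
        p = int((1 + np.sqrt(1 + 8 * m)) / 2)
        vals = vals[: p * (p - 1) // 2]
        if len(vals) < 1 or p < 2:
            return
        d = ld.consensus_cdf_auc(matrix_from_upper(vals))
        assert 0.0 <= d.auc <= 1.0


class TestDeltaAuc:
    def test_constant_sequence(self):
        out = ld.delta_auc([0.5, 0.5, 0.5])
        assert out[0] == 0.5 and np.allclose(out[1:], 0.0)

    def test_relative_and_absolute_conventions(self):
        assert ld.delta_auc([0.2, 0.4])[1] == pytest.approx(1.0)
        assert ld.delta_auc([0.2, 0.4], mode="absolute")[1] == pytest.approx(0.2)

    def test_output_length(self):
        assert len(ld.delta_auc([0.1, 0.2, 0.3, 0.4])) == 4


class TestClusterConsensus:
    def test_perfect_blocks_give_ones(self):
        upper = [1, 0, 0, 0, 0, 1]  # vars {0,1} and {2,3} perfect blocks
        M = matrix_from_upper(upper)
        vals = ld.cluster_consensus(M, np.array([0, 0, 1, 1]))
        assert np.allclose(vals, 1.0)

    def test_hand_built_two_plus_two(self):
        # upper triangle order: (0,1),(0,2),(0,3),(1,2),(1,3),(2,3)
        M = matrix_from_upper([0.8, 0.1, 0.2, 0.3, 0.4, 0.6])
        vals = ld.cluster_consensus(M, np.array([0, 0, 1, 1]))
        assert vals[0] == pytest.approx(0.8)  # single within pair (0,1)
        assert vals[1] == pytest.approx(0.6)  # single within pair (2,3)

    def test_singleton_cluster_warns_and_is_one(self):
        M = matrix_from_upper([0.5, 0.5, 0.5])
        with pytest.warns(UserWarning, match="singleton"):
            vals = ld.cluster_consensus(M, np.array([0, 0, 1]))
        assert vals[1] == 1.0

    def test_labels_must_cover_variables(self):
        M = matrix_from_upper([0.5, 0.5, 0.5])
        with pytest.raises(ValueError):
            ld.cluster_consensus(M, np.array([0, 0]))


class TestConsensusScore:
    def test_perfect_consensus_is_one(self):
        assert ld.consensus_score(matrix_from_upper([1, 0, 0, 0, 0, 1], K=2)) == 1.0

    def test_derived_three_index_case(self):
        # indices {0.9, 0.8, 0.1}, K=2: above = 0.85, below = 0.1, CS = 0.75
        assert ld.consensus_score(matrix_from_upper([0.9, 0.8, 0.1], K=2)) == pytest.approx(0.75)

    def test_indices_at_chance_give_near_zero(self):
        rng = np.random.default_rng(0)
        vals = 0.5 + rng.uniform(-0.01, 0.01, 6)
        assert abs(ld.consensus_score(matrix_from_upper(vals, K=2))) < 0.03


class TestFinalLabelsAndAgreement:
    def test_perfect_block_matrix_recovers_blocks(self):
        blocks = np.repeat([0, 1, 2], 5)
        M = ConsensusMatrix(
            indices=(blocks[:, None] == blocks[None, :]).astype(float),
            co_sample_counts=np.full((15, 15), 5.0),
            K=3,
            n_iterations=5,
            fraction=0.8,
        )
        labels = ld.final_labels(M, 3, seed=0)
        assert ld.adjusted_rand(labels, blocks) == 1.0
        assert len(np.unique(labels)) == 3
        assert np.array_equal(labels, ld.final_labels(M, 3, seed=0))

    def test_too_many_clusters_rejected(self):
        M = matrix_from_upper([1, 1, 1])
        with pytest.raises(ValueError):
            ld.final_labels(M, 5)


class TestAgreementIndices:
    def test_identical_partitions(self):
        a = np.array([0, 0, 1, 1, 2])
        assert ld.adjusted_rand(a, a) == 1.0
        assert ld.adjusted_mutual_info(a, a) == 1.0
        # label renaming is irrelevant
        assert ld.adjusted_rand(a, 1 - a % 2 + 10 * a) == pytest.approx(
            ld.adjusted_rand(a, a % 2 + 10 * a)
        )

    def test_hand_computed_ari(self):
        # a=[1,1,2,2], b=[1,2,1,2]: index 0, expected 2/3, max 2 -> -0.5
        assert ld.adjusted_rand([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(-0.5)

    def test_single_cluster_ami_zero(self):
        assert ld.adjusted_mutual_info([1, 1, 1, 1], [1, 1, 2, 2]) == pytest.approx(0.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ld.adjusted_rand([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            ld.adjusted_mutual_info([1, 2], [1, 2, 3])


def test_sweep_peaks_at_true_block_count(planted_3block):
    _, table, truth = planted_3block
    mats, diag = ld.consensus_sweep(
        table.values.to_numpy(), [2, 3, 4, 5], n_iter=60, seed=0
    )
    best_K = int(diag.loc[diag["consensus_score"].idxmax(), "K"])
    assert best_K == 3
    labels = ld.final_labels(mats[3], 3, seed=0)
    assert ld.adjusted_rand(labels, truth.cluster_labels) == 1.0
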