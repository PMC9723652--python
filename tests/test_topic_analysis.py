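import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu, spearmanr

import topicgrad as tg
from topicgrad.lda_engine import TopicModel


def toy_model(phi, theta=None, vocabulary=None):
    phi = np.asarray(phi, dtype=float)
    k, g = phi.shape
    if theta is None:
        theta = np.full((4, k), 1.0 / k)
    theta = np.asarray(theta, dtype=float)
    if vocabulary is None:
        vocabulary = np.array([f"G{i:02d}" for i in range(g)], dtype=object)
    return TopicModel(
        k=k, alpha=50.0, beta=0.1, theta=theta, phi=phi,
        vocabulary=np.asarray(vocabulary, dtype=object),
        cell_barcodes=np.array([f"c{j}" for j in range(theta.shape[0])],
                               dtype=object),
        seed=0, iterations=0, burn_in=0,
    )


class TestTopGenes:
    def test_full_ordering(self):
        model = toy_model([[0.1, 0.5, 0.4]], vocabulary=["B", "C", "A"])
        signature = tg.top_genes(model, 1, n=3)
        assert signature.genes == ["C", "A", "B"]

    def test_lexicographic_tie_break(self):
        model = toy_model([[0.4, 0.4, 0.2]], vocabulary=["B", "A", "Z"])
        assert tg.top_genes(model, 1, n=1).genes == ["A"]

    def test_out_of_range_topic(self):
        model = toy_model([[1.0]])
        with pytest.raises(tg.ValidationError):
            tg.top_genes(model, 2)

    def test_planted_anchors_recovered(self, small_planted, small_model):
        _, truth = small_planted
        perm, _ = tg.match_topics(small_model.phi, truth.phi_true)
        for topic in range(small_model.k):
            anchors = set(truth.anchor_genes[perm[topic]])
            signature = set(tg.top_genes(small_model, topic + 1, n=20).genes)
            assert len(signature & anchors) / len(anchors) >= 0.9


class TestNormalizeCellScores:
    def test_hand_zscore(self):
        model = toy_model([[1.0]], theta=[[0.2], [0.4]])
        table = tg.normalize_cell_scores(model)
        np.testing.assert_allclose(
            table.scores["Topic_1"].to_numpy(), [-0.7071067811865476, 0.7071067811865476])
        assert table.score_kind == "z_theta"

    def test_columns_centered_unit_variance(self, small_model):
        table = tg.normalize_cell_scores(small_model)
        values = table.scores.to_numpy()
        np.testing.assert_allclose(values.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(values.std(axis=0, ddof=1), 1.0, atol=1e-6)

    def test_constant_column_warns_and_zeroes(self):
        model = toy_model([[1.0]], theta=[[1.0], [1.0], [1.0]])
        with pytest.warns(UserWarning, match="constant"):
            table = tg.normalize_cell_scores(model)
        assert table.scores["Topic_1"].to_numpy().tolist() == [0.0, 0.0, 0.0]

    def test_single_cell_rejected(self):
        model = toy_model([[1.0]], theta=[[1.0]])
        with pytest.raises(tg.ValidationError):
            tg.normalize_cell_scores(model)


class TestSignatureScore:
    def test_flat_expression_scores_zero(self):
        counts = tg.CountMatrix(
            np.full((30, 8), 5), [f"G{i:02d}" for i in range(30)],
            [f"c{j}" for j in range(8)])
        scores = tg.signature_score(counts, ["G00", "G01"], seed=0)
        np.testing.assert_allclose(scores, 0.0, atol=1e-12)

    def test_whole_universe_signature_near_zero(self):
        rng = np.random.default_rng(3)
        counts = tg.CountMatrix(
            rng.poisson(5.0, size=(40, 12)), [f"G{i:02d}" for i in range(40)],
            [f"c{j}" for j in range(12)])
        scores = tg.signature_score(
            counts, list(counts.gene_names), n_ctrl=200, seed=0)
        assert np.max(np.abs(scores)) < 0.15

    def test_upregulated_signature_separates_cells(self):
        # signature genes are 4x up in planted responder cells; 60 flat genes
        # share their expression bin so the sampled controls are informative
        # (controls collapse onto the signature itself when it sits alone in
        # the top bin, which would null the score by construction)
        rng = np.random.default_rng(11)
        n_genes, n_cells = 200, 200
        base = rng.poisson(4.0, size=(n_genes, n_cells))
        hot = rng.random(n_cells) < 0.5  # planted responders
        signature = [f"G{i:03d}" for i in range(10)]
        base[:10, hot] = rng.poisson(16.0, size=(10, hot.sum()))  # 4x up
        base[10:70, :] = rng.poisson(10.0, size=(60, n_cells))  # bin-mates
        counts = tg.CountMatrix(base, [f"G{i:03d}" for i in range(n_genes)],
                                [f"c{j}" for j in range(n_cells)])
        scores = tg.signature_score(counts, signature, n_bins=10, seed=2)
        u = mannwhitneyu(scores[hot], scores[~hot]).statistic
        auc = u / (hot.sum() * (~hot).sum())
        assert auc >= 0.9

    def test_absent_genes_warn_all_absent_raise(self, tiny_counts):
        with pytest.warns(UserWarning, match="absent"):
            tg.signature_score(tiny_counts, ["GA", "NOPE"], seed=0)
        with pytest.raises(tg.ValidationError):
            tg.signature_score(tiny_counts, ["NOPE"], seed=0)

    def test_cell_permutation_equivariance(self):
        rng = np.random.default_rng(8)
        counts = rng.poisson(5.0, size=(60, 30))
        names = [f"G{i:02d}" for i in range(60)]
        barcodes = [f"c{j}" for j in range(30)]
        matrix = tg.CountMatrix(counts, names, barcodes)
        perm = rng.permutation(30)
        permuted = tg.CountMatrix(counts[:, perm], names,
                                  [barcodes[j] for j in perm])
        a = tg.signature_score(matrix, names[:5], seed=4)
        b = tg.signature_score(permuted, names[:5], seed=4)
        np.testing.assert_allclose(b, a[perm], atol=1e-12)


class TestTransferTopics:
    def test_self_transfer_rank_correlates_with_theta(
            self, small_planted, small_model):
        matrix, _ = small_planted
        table = tg.transfer_topics(small_model, matrix, n=20, seed=0)
        assert table.score_kind == "signature"
        for topic in range(small_model.k):
            rho = spearmanr(
                table.scores[f"Topic_{topic + 1}"].to_numpy(),
                small_model.theta[:, topic],
            ).statistic
            assert rho > 0

    def test_disjoint_target_drops_all_columns(self, small_model):
        target = tg.CountMatrix(
            np.ones((5, 4), dtype=int), [f"OTHER{i}" for i in range(5)],
            [f"t{j}" for j in range(4)])
        with pytest.warns(UserWarning, match="no genes"):
            table = tg.transfer_topics(small_model, target, n=10, seed=0)
        assert table.scores.shape[1] == 0


class TestTopicOverlap:
    def test_self_overlap_diagonal(self, small_model):
        overlap = tg.topic_overlap(small_model, small_model, n=15)
        np.testing.assert_array_equal(np.diag(overlap), 15)
        assert overlap.max() <= 15

    def test_disjoint_vocabularies_all_zero(self):
        a = toy_model([[0.6, 0.4]], vocabulary=["A1", "A2"])
        b = toy_model([[0.5, 0.5]], vocabulary=["B1", "B2"])
        assert tg.topic_overlap(a, b, n=2).tolist() == [[0]]


class TestDeltaControlZscore:
    def test_control_median_exactly_zero(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=40)
        groups = np.array(["ctrl"] * 20 + ["treat"] * 20, dtype=object)
        deltas = tg.delta_control_zscore(scores, groups, "ctrl")
        assert np.median(deltas[groups == "ctrl"]) == 0.0

    def test_shifted_group_has_positive_median(self):
        rng = np.random.default_rng(1)
        scores = np.concatenate([
            rng.normal(0.0, 1.0, 200), rng.normal(2.0, 1.0, 200)])
        groups = np.array(["ctrl"] * 200 + ["treat"] * 200, dtype=object)
        deltas = tg.delta_control_zscore(scores, groups, "ctrl")
        median = np.median(deltas[groups == "treat"])
        assert 1.0 < median < 2.0  # ~2 raw sd compressed by global z-scoring

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=30)
        groups = np.array(["a"] * 15 + ["b"] * 15, dtype=object)
        base = tg.delta_control_zscore(scores, groups, "a")
        shifted = tg.delta_control_zscore(5.0 + 3.0 * scores, groups, "a")
        np.testing.assert_allclose(shifted, base, atol=1e-9)

    def test_all_control_median_zero(self):
        scores = np.array([1.0, 2.0, 3.0])
        groups = np.array(["c", "c", "c"], dtype=object)
        deltas = tg.delta_control_zscore(scores, groups, "c")
        assert np.median(deltas) == 0.0

    def test_errors(self):
        with pytest.raises(tg.ValidationError):
            tg.delta_control_zscore([1.0, 2.0], ["a", "b"], "missing")
        with pytest.raises(tg.ValidationError):
            tg.delta_control_zscore([1.0, 1.0], ["a", "b"], "a")
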