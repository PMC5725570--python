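"""Marker scoring, cluster labelling, classifier and embedding behaviour."""

import numpy as np
import pandas as pd
import pytest

from rgepdeconv.containers import LOG2, ExpressionMatrix, MarkerSpec
from rgepdeconv.classify import (
    ClassifyParams,
    ClusterAssignment,
    classify_cells,
    classify_two_stage,
    cluster_dbscan,
    cross_validate,
    embed_tsne,
    label_clusters,
    score_markers,
    train_classifier,
)


def log_matrix(values, genes, cells=None):
    cells = cells or [f"c{j}" for j in range(np.asarray(values).shape[1])]
    return ExpressionMatrix(pd.DataFrame(np.asarray(values, float),
                                         index=genes, columns=cells), LOG2)


class TestScoreMarkers:
    def test_hand_arithmetic_oracle(self):
        """AND gene (0,2,4) and NOT gene (4,0,0) give scores (0, 0.5, 1)."""
        m = log_matrix([[0, 2, 4], [4, 0, 0]], genes=["a", "n"])
        spec = MarkerSpec({"T": {"AND": ["a"], "NOT": ["n"]}})
        scores = score_markers(m, spec)["T"]
        np.testing.assert_allclose(scores.to_numpy(), [0.0, 0.5, 1.0])

    def test_all_and_at_max_scores_one(self):
        m = log_matrix([[5, 0], [3, 0]], genes=["a1", "a2"])
        spec = MarkerSpec({"T": {"AND": ["a1", "a2"]}})
        assert score_markers(m, spec)["T"].iloc[0] == pytest.approx(1.0)

    def test_single_zero_and_gene_kills_score(self):
        """AND genes are all required: one silent AND gene gates to zero."""
        m = log_matrix([[5, 5], [3, 0]], genes=["a1", "a2"])
        spec = MarkerSpec({"T": {"AND": ["a1", "a2"]}})
        assert score_markers(m, spec)["T"].iloc[1] == 0.0

    def test_or_takes_maximum(self):
        m = log_matrix([[4, 0], [0, 2]], genes=["o1", "o2"])
        spec = MarkerSpec({"T": {"OR": ["o1", "o2"]}})
        np.testing.assert_allclose(score_markers(m, spec)["T"], [1.0, 1.0])

    def test_type_without_positive_markers_rejected(self):
        m = log_matrix([[1, 2]], genes=["n"])
        with pytest.raises(ValueError, match="neither AND nor OR"):
            score_markers(m, MarkerSpec({"T": {"NOT": ["n"]}}))

    def test_overlapping_lists_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            MarkerSpec({"T": {"AND": ["g"], "NOT": ["g"]}})


def assignment(cluster_ids, cells):
    emb = pd.DataFrame(0.0, index=cells, columns=["x", "y"])
    return ClusterAssignment(pd.Series(cluster_ids, index=cells), emb)


class TestLabelClusters:
    def test_predominant_type_assigned(self):
        """Totals (10, 5): 5 < 7.5, only the first type passes."""
        cells = ["c1", "c2"]
        scores = pd.DataFrame({"A": [5.0, 5.0], "B": [2.5, 2.5]}, index=cells)
        labels = label_clusters(scores, assignment([0, 0], cells))
        assert list(labels) == ["A", "A"]

    def test_ambiguous_cluster_left_unlabelled(self):
        """Totals (10, 8): both exceed 7.5, so neither is assigned."""
        cells = ["c1", "c2"]
        scores = pd.DataFrame({"A": [5.0, 5.0], "B": [4.0, 4.0]}, index=cells)
        labels = label_clusters(scores, assignment([0, 0], cells))
        assert labels.isna().all()

    def test_noise_cells_unlabelled(self):
        cells = ["c1", "c2", "c3"]
        scores = pd.DataFrame({"A": [5.0, 5.0, 9.9]}, index=cells)
        labels = label_clusters(scores, assignment([0, 0, -1], cells))
        assert list(labels[:2]) == ["A", "A"] and labels.iloc[2] is None

    def test_single_type_spec_labels_every_cluster(self):
        cells = [f"c{i}" for i in range(6)]
        scores = pd.DataFrame({"A": np.ones(6)}, index=cells)
        labels = label_clusters(scores, assignment([0, 0, 0, 1, 1, 1], cells))
        assert (labels == "A").all()

    def test_never_assigns_two_types_to_one_cluster(self):
        rng = np.random.default_rng(0)
        cells = [f"c{i}" for i in range(30)]
        scores = pd.DataFrame(rng.random((30, 4)), index=cells,
                              columns=list("ABCD"))
        labels = label_clusters(scores, assignment([i % 3 for i in range(30)], cells))
        for cid in range(3):
            got = set(labels[np.arange(30) % 3 == cid].dropna())
            assert len(got) <= 1


class TestDBSCAN:
    def test_two_far_blobs_found_exactly(self):
        """Two 30-point blobs at distance 141 >> eps: brute-force check says
        every point is core, so exactly 2 clusters and no noise."""
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.1, (30, 2))
        b = rng.normal(100, 0.1, (30, 2))
        pts = np.vstack([a, b])
        # independent neighbourhood oracle
        d = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        assert ((d < 1.5).sum(axis=1) >= 25).all()
        emb = pd.DataFrame(pts, columns=["x", "y"])
        asg = cluster_dbscan(emb, min_pts=25, eps=1.5)
        assert set(asg.labels) == {0, 1}

    def test_identical_points_one_cluster(self):
        emb = pd.DataFrame(np.zeros((40, 2)), columns=["x", "y"])
        asg = cluster_dbscan(emb)
        assert set(asg.labels) == {0}

    def test_too_few_points_all_noise(self):
        emb = pd.DataFrame(np.zeros((10, 2)), columns=["x", "y"])
        asg = cluster_dbscan(emb, min_pts=25)
        assert (asg.labels == -1).all()

    def test_nonfinite_embedding_rejected(self):
        emb = pd.DataFrame([[0.0, np.nan]], columns=["x", "y"])
        with pytest.raises(ValueError, match="non-finite"):
            cluster_dbscan(emb)


class TestEmbedTsne:
    @pytest.fixture(scope="class")
    def two_blob_matrix(self):
        rng = np.random.default_rng(0)
        n = 80
        base = np.zeros((20, n))
        base[:10, : n // 2] = 6.0
        base[10:, n // 2:] = 6.0
        vals = np.clip(base + rng.normal(0, 0.3, base.shape), 0, None)
        return log_matrix(vals, genes=[f"g{i}" for i in range(20)])

    def test_deterministic_given_seed(self, two_blob_matrix):
        e1 = embed_tsne(two_blob_matrix, perplexity=10, seed=4)
        e2 = embed_tsne(two_blob_matrix, perplexity=10, seed=4)
        pd.testing.assert_frame_equal(e1, e2)

    def test_separated_types_form_clusters(self, two_blob_matrix):
        emb = embed_tsne(two_blob_matrix, perplexity=10, seed=0)
        asg = cluster_dbscan(emb, min_pts=8, eps=6.0)
        assert len(set(asg.labels) - {-1}) >= 2

    def test_too_few_cells_rejected(self):
        m = log_matrix(np.ones((5, 10)), genes=[f"g{i}" for i in range(5)])
        with pytest.raises(ValueError, match="perplexity"):
            embed_tsne(m, perplexity=30)


class TestClassifier:
    @pytest.fixture(scope="class")
    def separable(self):
        rng = np.random.default_rng(1)
        n = 60
        vals = np.zeros((10, n))
        vals[:5, : n // 2] = 8.0
        vals[5:, n // 2:] = 8.0
        vals = np.clip(vals + rng.normal(0, 0.2, vals.shape), 0, None)
        m = log_matrix(vals, genes=[f"g{i}" for i in range(10)])
        labels = pd.Series(["A"] * (n // 2) + ["B"] * (n // 2), index=m.column_ids)
        return m, labels

    def test_separable_training_is_perfect(self, separable):
        m, labels = separable
        clf = train_classifier(m, labels, seed=0)
        assert (classify_cells(clf, m) == labels).all()

    def test_single_class_rejected(self, separable):
        m, labels = separable
        with pytest.raises(ValueError, match="two labelled classes"):
            train_classifier(m, labels.where(labels == "A"))

    def test_impure_leaf_below_threshold_is_unknown(self):
        """Cells indistinguishable to the tree land in a 60/40 leaf."""
        vals = np.ones((3, 10))
        m = log_matrix(vals, genes=["g0", "g1", "g2"])
        labels = pd.Series(["A"] * 6 + ["B"] * 4, index=m.column_ids)
        clf = train_classifier(m, labels, seed=0)
        preds = classify_cells(clf, m)
        assert (preds == "unknown").all()

    def test_prediction_invariant_to_gene_row_order(self, separable):
        m, labels = separable
        clf = train_classifier(m, labels, seed=0)
        shuffled = ExpressionMatrix(m.values.iloc[::-1], LOG2)
        pd.testing.assert_series_equal(classify_cells(clf, m),
                                       classify_cells(clf, shuffled))

    def test_empty_matrix_empty_annotation(self, separable):
        m, labels = separable
        clf = train_classifier(m, labels, seed=0)
        empty = ExpressionMatrix(m.values.iloc[:, :0], LOG2)
        assert len(classify_cells(clf, empty)) == 0

    def test_missing_genes_reported(self, separable):
        m, labels = separable
        clf = train_classifier(m, labels, seed=0)
        smaller = ExpressionMatrix(m.values.iloc[:3], LOG2)
        with pytest.raises(ValueError, match="lacks classifier genes"):
            classify_cells(clf, smaller)


class TestCrossValidate:
    def test_separable_data_perfect_accuracy(self):
        rng = np.random.default_rng(0)
        vals = np.hstack([np.full((4, 30), 8.0), np.zeros((4, 30))])
        vals += rng.normal(0, 0.1, vals.shape)
        m = log_matrix(np.clip(vals, 0, None), genes=list("wxyz"))
        labels = pd.Series(["A"] * 30 + ["B"] * 30, index=m.column_ids)
        assert cross_validate(m, labels, k=5, seed=0) == 1.0

    def test_chance_level_on_noise_features(self):
        """Pure-noise features: accuracy within exact binomial bounds of 0.5."""
        rng = np.random.default_rng(7)
        m = log_matrix(rng.random((10, 200)) * 5, genes=[f"g{i}" for i in range(10)])
        labels = pd.Series(["A", "B"] * 100, index=m.column_ids)
        acc = cross_validate(m, labels, k=5, seed=0)
        assert 0.35 <= acc <= 0.65

    def test_single_class_rejected(self):
        m = log_matrix(np.ones((2, 10)), genes=["a", "b"])
        labels = pd.Series(["A"] * 10, index=m.column_ids)
        with pytest.raises(ValueError, match="two classes"):
            cross_validate(m, labels, k=2)

    def test_class_smaller_than_k_rejected(self):
        m = log_matrix(np.ones((2, 10)), genes=["a", "b"])
        labels = pd.Series(["A"] * 7 + ["B"] * 3, index=m.column_ids)
        with pytest.raises(ValueError, match="smaller than k"):
            cross_validate(m, labels, k=5)


class TestTwoStage:
    def test_cohort_without_t_cells_keeps_stage1(self):
        """With no cells labelled T, stage 2 is skipped with a warning."""
        rng = np.random.default_rng(2)
        n = 80
        vals = np.zeros((12, n))
        vals[0:2, : n // 2] = 8.0     # B markers
        vals[2:4, n // 2:] = 8.0      # NK markers
        vals[4:, :] = np.clip(rng.normal(3, 1, (8, n)), 0, None)
        vals = np.clip(vals + rng.normal(0, 0.2, vals.shape), 0, None)
        genes = ["b1", "b2", "nk1", "nk2"] + [f"g{i}" for i in range(8)]
        m = log_matrix(vals, genes=genes)
        spec = MarkerSpec({"B cell": {"AND": ["b1"], "OR": ["b2"]},
                           "NK cell": {"AND": ["nk1"], "OR": ["nk2"]}})
        tsub = MarkerSpec({"CD4 T cell": {"AND": ["g0"]}})
        params = ClassifyParams(perplexity=15, min_pts=10, eps=8.0, seed=0)
        with pytest.warns(UserWarning, match="no T cells"):
            merged, s1, s2 = classify_two_stage(m, spec, tsub, params)
        assert s2 is None
        pd.testing.assert_series_equal(merged, s1.annotation)
        assert not set(merged) & {"CD4 T cell"}
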