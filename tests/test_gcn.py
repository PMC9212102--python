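import numpy as np
import pytest
from sklearn.exceptions import NotFittedError
from sklearn.model_selection import train_test_split

from connectogcn.connectome import fisher_z, pearson_connectivity
from connectogcn.evaluate import confusion_metrics
from connectogcn.gcn import GCNClassifier, aggregate_saliency, gcn_forward
from connectogcn.graphs import SubjectGraph, normalize_adjacency
from connectogcn.synth import SynthConfig, generate_cohort


def make_cohort_arrays(
    effect=0.5, n_per_group=50, a=24, seed=0, timepoints=120
):
    cfg = SynthConfig(
        n_regions=a,
        n_sites=2,
        site_sizes=((0, n_per_group), (n_per_group, 2)),
        n_timepoints=timepoints,
        signal_nodes=tuple(range(4, 10)),
        effect_size=effect,
        site_shift=0.0,
        site_scale=0.0,
        seed=seed,
    )
    recs, series = generate_cohort(cfg)
    y = np.array([r.diagnosis for r in recs])
    Z = np.stack(
        [fisher_z(pearson_connectivity(ts.values)).values for ts in series]
    )
    return cfg, Z, y


def hand_model(theta, w, b, classes=("control", "patient")):
    """Assemble a GCNClassifier with fixed weights, bypassing training."""
    clf = GCNClassifier(hidden=(theta.shape[1],))
    clf.weights_ = [theta.astype(np.float32)]
    clf.head_weight_ = w.astype(np.float32)
    clf.head_bias_ = b.astype(np.float32)
    clf.classes_ = np.array(classes)
    clf.n_features_in_ = theta.shape[0]
    clf.n_nodes_ = 2
    clf.history_ = []
    return clf


class TestForwardPass:
    def test_pencil_and_paper_forward(self):
        # 2 nodes, 2 input features, 1 conv layer of width 2
        X = np.array([[1.0, 2.0], [3.0, -1.0]])
        W = np.array([[0.0, 1.0], [1.0, 0.0]])
        A = normalize_adjacency(W)  # [[.5,.5],[.5,.5]]
        theta = np.array([[1.0, 0.5], [-1.0, 2.0]])
        w = np.array([[1.0, -1.0], [0.5, 1.0]])
        b = np.array([0.125, -0.25])  # dyadic: exact in single precision
        graph = SubjectGraph("s", X, W, A)

        H0A = A @ X  # [[2, .5],[2, .5]]
        H1 = np.maximum(H0A @ theta, 0)  # relu([[1.5,2],[1.5,2]])
        pooled = H1.mean(axis=0)
        expected = w @ pooled + b

        clf = hand_model(theta, w, b)
        logits, maps = gcn_forward(clf, graph)
        assert np.allclose(logits, expected, atol=1e-10)
        assert np.allclose(maps, H1, atol=1e-10)

    def test_dead_network_outputs_biases(self):
        X = np.ones((2, 2))
        W = np.array([[0.0, 1.0], [1.0, 0.0]])
        graph = SubjectGraph("s", X, W, normalize_adjacency(W))
        b = np.array([0.25, -0.75])  # dyadic: exact in single precision
        clf = hand_model(np.zeros((2, 2)), np.zeros((2, 2)), b)
        logits, maps = gcn_forward(clf, graph)
        assert np.allclose(logits, b, atol=1e-12)
        assert np.all(maps == 0)

    def test_width_mismatch_rejected(self):
        X = np.ones((3, 3))
        W = np.zeros((3, 3))
        graph = SubjectGraph("s", X, W, normalize_adjacency(W))
        clf = hand_model(np.zeros((2, 2)), np.zeros((2, 2)), np.zeros(2))
        with pytest.raises(ValueError, match="width"):
            gcn_forward(clf, graph)

    def test_node_permutation_invariance_of_logits(self, rng):
        """Reordering the nodes (graph rows) leaves the GAP logits unchanged."""
        _, Z, y = make_cohort_arrays(n_per_group=12, a=12, seed=3)
        clf = GCNClassifier(hidden=(8,), max_epochs=10, k=4, seed=0).fit(Z, y)
        perm = rng.permutation(12)
        logits = clf.decision_function(Z[:4])
        logits_p = clf.decision_function(Z[:4][:, perm, :])
        assert np.allclose(logits, logits_p, atol=1e-8)


class TestTraining:
    def test_seeded_determinism(self):
        _, Z, y = make_cohort_arrays(n_per_group=15, a=12, seed=4)
        a = GCNClassifier(hidden=(8, 8), max_epochs=15, k=4, seed=9).fit(Z, y)
        b = GCNClassifier(hidden=(8, 8), max_epochs=15, k=4, seed=9).fit(Z, y)
        for wa, wb in zip(a.weights_, b.weights_):
            assert np.array_equal(wa, wb)
        assert np.array_equal(a.head_weight_, b.head_weight_)
        assert [h["train_loss"] for h in a.history_] == [
            h["train_loss"] for h in b.history_
        ]

    def test_separable_cohort_reaches_full_training_accuracy(self):
        _, Z, y = make_cohort_arrays(effect=0.5, n_per_group=40, a=24, seed=5)
        clf = GCNClassifier(hidden=(16, 16), k=6, seed=0).fit(Z, y)
        bacc, _, _ = confusion_metrics(clf.predict(Z), y)
        assert bacc == 100.0

    def test_shuffled_labels_give_chance_level(self):
        _, Z, y = make_cohort_arrays(effect=0.5, n_per_group=60, a=16, seed=6)
        rng = np.random.default_rng(0)
        y_shuf = rng.permutation(y)
        tr, te = train_test_split(
            np.arange(len(y)), test_size=100, stratify=y_shuf, random_state=0
        )
        clf = GCNClassifier(hidden=(8,), max_epochs=40, k=5, seed=0)
        clf.fit(Z[tr], y_shuf[tr])
        bacc, _, _ = confusion_metrics(clf.predict(Z[te]), y_shuf[te])
        assert abs(bacc - 50.0) <= 10.0

    def test_loss_decreases_over_training(self):
        _, Z, y = make_cohort_arrays(effect=0.5, n_per_group=25, a=12, seed=7)
        clf = GCNClassifier(hidden=(8,), max_epochs=30, k=4, seed=0).fit(Z, y)
        losses = [h["train_loss"] for h in clf.history_]
        assert losses[-1] < losses[0]

    def test_single_class_rejected(self):
        _, Z, y = make_cohort_arrays(n_per_group=10, a=10, seed=8)
        with pytest.raises(ValueError, match="2 classes"):
            GCNClassifier(max_epochs=2).fit(Z, np.array(["control"] * len(y)))

    def test_unfitted_predict_rejected(self):
        with pytest.raises(NotFittedError):
            GCNClassifier().predict(np.zeros((1, 4, 4)))


class TestPredictProba:
    def test_rows_sum_to_one_and_match_forward(self):
        _, Z, y = make_cohort_arrays(n_per_group=12, a=12, seed=9)
        clf = GCNClassifier(hidden=(8,), max_epochs=10, k=4, seed=1).fit(Z, y)
        proba = clf.predict_proba(Z[:5])
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-9)
        assert np.all((proba > 0) & (proba < 1))
        logits = clf.decision_function(Z[:5])
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        assert np.allclose(proba, e / e.sum(axis=1, keepdims=True), atol=1e-12)

    def test_symmetric_logits_give_half(self):
        X = np.ones((2, 2))
        W = np.array([[0.0, 1.0], [1.0, 0.0]])
        graph = SubjectGraph("s", X, W, normalize_adjacency(W))
        clf = hand_model(np.zeros((2, 2)), np.zeros((2, 2)), np.zeros(2))
        assert np.allclose(clf.predict_proba([graph]), 0.5, atol=1e-12)


class TestCam:
    def test_gap_cam_identity(self):
        _, Z, y = make_cohort_arrays(n_per_group=20, a=16, seed=10)
        clf = GCNClassifier(hidden=(8, 8), max_epochs=15, k=5, seed=2).fit(Z, y)
        ci = list(clf.classes_).index("patient")
        scores = clf.cam_scores(Z[:8], target_class="patient")
        logits = clf.decision_function(Z[:8])
        lhs = scores.mean(axis=1)
        rhs = logits[:, ci] - clf.head_bias_[ci]
        assert np.abs(lhs - rhs).max() < 1e-8

    def test_zero_feature_maps_give_zero_scores(self):
        X = np.ones((2, 2))
        W = np.array([[0.0, 1.0], [1.0, 0.0]])
        graph = SubjectGraph("s", X, W, normalize_adjacency(W))
        clf = hand_model(np.zeros((2, 2)), np.ones((2, 2)), np.zeros(2))
        assert np.all(clf.cam_scores([graph], target_class="patient") == 0)

    def test_architecture_violation_rejected(self):
        _, Z, y = make_cohort_arrays(n_per_group=10, a=10, seed=11)
        clf = GCNClassifier(hidden=(8,), max_epochs=3, k=3, seed=0).fit(Z, y)
        clf.head_weight_ = np.zeros((2, 5), dtype=np.float32)  # tampered head
        with pytest.raises(ValueError, match="linear head"):
            clf.cam_scores(Z[:2])


class TestAggregateSaliency:
    def test_single_subject_ranking(self):
        scores = np.array([[0.1, 0.9, -0.5, 0.3]])
        sal = aggregate_saliency(scores, top_k=2, mode="signed")
        assert sal.ranking.tolist() == [1, 3, 0, 2]
        assert sal.top_regions.tolist() == [1, 3]

    def test_abs_mode_ranks_by_magnitude(self):
        scores = np.array([[0.1, -0.9, 0.5, 0.0]])
        sal = aggregate_saliency(scores, top_k=2, mode="abs")
        assert sal.ranking.tolist() == [1, 2, 0, 3]

    def test_opposite_subjects_cancel_ties_by_index(self):
        scores = np.array([[1.0, -2.0, 3.0], [-1.0, 2.0, -3.0]])
        sal = aggregate_saliency(scores, top_k=3)
        assert np.allclose(sal.mean_activation, 0.0)
        assert sal.ranking.tolist() == [0, 1, 2]

    def test_top_k_of_90(self, rng):
        sal = aggregate_saliency(rng.normal(size=(5, 90)), top_k=10)
        assert len(sal.top_regions) == 10
        frame = sal.to_frame()
        assert list(frame["rank"]) == list(range(1, 91))

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="no saliency"):
            aggregate_saliency(np.empty((0, 0)))
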