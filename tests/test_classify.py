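from itertools import combinations, product

import numpy as np
import pytest

from benthoscan import classify as clf


def _blobs(k, n_per=40, d=6, sep=8.0, seed=0):
    rng = np.random.default_rng(seed)
    X, y = [], []
    for i in range(k):
        c = np.zeros(d)
        c[i % d] = sep * (1 + i // d)
        X.append(rng.normal(c, 0.4, size=(n_per, d)))
        y += [i] * n_per
    return np.vstack(X), np.array(y)


class TestSelectK:
    @pytest.mark.parametrize("k_true", [2, 3, 4, 5])
    def test_recovers_generative_k(self, k_true):
        X, _ = _blobs(k_true)
        assert clf.select_k(X, 2, 8, seed=0) == k_true

    def test_degenerate_returns_k_min_with_warning(self):
        X = np.zeros((10, 3))
        with pytest.warns(UserWarning):
            assert clf.select_k(X, 2, 5) == 2


class TestKMeans:
    def test_points_equal_centroids(self):
        X, y = _blobs(3)
        model = clf.fit_kmeans(X, 3, seed=0)
        # centroids (de-standardized) predict to themselves
        cents_raw = model.centroids * model.feature_stds + model.feature_means
        pred = model.predict(cents_raw)
        assert sorted(pred) == [0, 1, 2]

    def test_row_order_invariance(self):
        X, _ = _blobs(3, seed=2)
        model = clf.fit_kmeans(X, 3, seed=0)
        perm = np.random.default_rng(0).permutation(len(X))
        a = clf.predict_clusters(model, X)[perm]
        b = clf.predict_clusters(model, X[perm])
        assert np.array_equal(a, b)

    def test_silhouette_recorded(self):
        X, _ = _blobs(4)
        model = clf.fit_kmeans(X, 4, seed=0)
        # three informative axes out of six: well over zero but the noise
        # dimensions keep it below the clean-blob ceiling
        assert -1.0 <= model.training_silhouette <= 1.0
        assert model.training_silhouette > 0.5


class TestSupervised:
    def test_separable_data_perfect_train_accuracy(self):
        X, y = _blobs(3)
        labels = np.array(list("ABC"))[y]
        backend = clf.train_supervised(X, labels)
        assert (backend.predict(X) == labels).mean() == 1.0

    def test_predict_proba_rows_sum_to_one(self):
        X, y = _blobs(4)
        backend = clf.train_supervised(X, y)
        proba = backend.predict_proba(X)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_degenerate_class_set_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 4))
        with pytest.raises(ValueError, match="degenerate class set"):
            clf.train_supervised(X, np.zeros(20))

    def test_loss_curve_decreases(self):
        X, y = _blobs(3, n_per=60)
        backend = clf.train_supervised(X, y)
        curve = np.array(backend.loss_curve_)
        assert len(curve) > 1
        # smoothed trend is decreasing
        w = max(len(curve) // 5, 1)
        smooth = np.convolve(curve, np.ones(w) / w, mode="valid")
        assert smooth[-1] < smooth[0]

    def test_heldout_f1_on_separated_blobs(self):
        X, y = _blobs(4, n_per=80, seed=5)
        labels = np.array(list("ABCD"))[y]
        rng = np.random.default_rng(0)
        idx = rng.permutation(len(X))
        tr, te = idx[:240], idx[240:]
        backend = clf.train_supervised(X[tr], labels[tr])
        cm = clf.confusion(labels[te], backend.predict(X[te]))
        assert clf.f1_macro(cm) >= 0.9


class TestConfusion:
    def test_counts_and_row_sums(self):
        cm = clf.confusion(["A", "A", "B", "B", "B"], ["A", "B", "B", "B", "A"])
        assert cm.loc["A", "A"] == 1
        assert cm.loc["A", "B"] == 1
        assert cm.loc["B", "B"] == 2
        assert cm.sum(axis=1).tolist() == [2, 3]

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            clf.confusion([1], [1, 2])


class TestF1:
    def test_perfect(self):
        cm = clf.confusion([0, 1, 0, 1], [0, 1, 0, 1])
        scores = clf.f1_scores(cm)
        assert scores["f1_macro"] == pytest.approx(1.0)
        assert scores["f1_weighted"] == pytest.approx(1.0)

    def test_closed_form_constructed_matrix(self):
        # confusion [[8, 2], [4, 6]]: per-class F1 = 16/22 and 12/18
        import pandas as pd

        cm = pd.DataFrame([[8, 2], [4, 6]], index=["a", "b"], columns=["a", "b"])
        scores = clf.f1_scores(cm)
        f1_a = 2 * (8 / 12) * (8 / 10) / ((8 / 12) + (8 / 10))
        f1_b = 2 * (6 / 8) * (6 / 10) / ((6 / 8) + (6 / 10))
        assert scores["f1_a"] == pytest.approx(f1_a)
        assert scores["f1_b"] == pytest.approx(f1_b)
        assert scores["f1_macro"] == pytest.approx((f1_a + f1_b) / 2)


class TestKappa:
    def test_identical_is_one(self):
        y = ["A", "B", "C", "A"]
        assert clf.cohens_kappa(y, y) == pytest.approx(1.0)

    def test_chance_level_is_zero(self):
        # agreement exactly at the chance rate: po == pe
        a = ["x", "x", "y", "y"]
        b = ["x", "y", "x", "y"]
        assert clf.cohens_kappa(a, b) == pytest.approx(0.0)

    def test_symmetric(self):
        rng = np.random.default_rng(0)
        a = rng.choice(list("ABC"), 50).tolist()
        b = rng.choice(list("ABC"), 50).tolist()
        assert clf.cohens_kappa(a, b) == pytest.approx(clf.cohens_kappa(b, a))

    def test_bounded(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = rng.choice([0, 1], 20).tolist()
            b = rng.choice([0, 1], 20).tolist()
            assert -1.0 - 1e-12 <= clf.cohens_kappa(a, b) <= 1.0 + 1e-12


def _fmi_brute(a, b):
    """Pair-counting oracle: enumerate all C(n,2) pairs."""
    n = len(a)
    tp = fp = fn = 0
    for i, j in combinations(range(n), 2):
        same_a = a[i] == a[j]
        same_b = b[i] == b[j]
        tp += same_a and same_b
        fp += same_b and not same_a
        fn += same_a and not same_b
    if tp == 0:
        return 0.0
    prec = tp / (tp + fp)
    rec = tp / (tp + fn)
    return float(np.sqrt(prec * rec))


class TestFMI:
    def test_identical_partitions(self):
        y = [1, 1, 2, 2, 3]
        assert clf.fowlkes_mallows(y, y) == pytest.approx(1.0)

    def test_example_partition_vs_brute_force(self):
        a = [1, 1, 2, 2]
        b = [1, 2, 1, 2]
        assert clf.fowlkes_mallows(a, b) == pytest.approx(_fmi_brute(a, b))

    def test_all_partitions_up_to_6_items(self):
        # implementation equals the brute-force oracle on every labeling
        # of <= 6 items over up to 3 labels
        for n in (3, 4, 5, 6):
            for a in product(range(2), repeat=n):
                for b in product(range(3), repeat=n):
                    assert clf.fowlkes_mallows(list(a), list(b)) == pytest.approx(
                        _fmi_brute(a, b)
                    ), (a, b)

    def test_label_permutation_invariance(self):
        a = [0, 0, 1, 1, 2]
        b = [2, 2, 0, 0, 1]  # same partition, renamed labels
        assert clf.fowlkes_mallows(a, b) == pytest.approx(1.0)


class TestConfidence:
    def test_one_hot_classifier(self):
        proba = np.eye(4)[np.array([0, 1, 2, 3, 0])]
        df = clf.confidence_distribution(proba, np.array(list("ABCD")))
        assert (df["q50"].dropna() == 1.0).all()

    def test_uniform_classifier(self):
        proba = np.full((10, 4), 0.25)
        df = clf.confidence_distribution(proba, np.array(list("ABCD")))
        got = df[df["n"] > 0]
        assert np.allclose(got["q50"], 0.25)
        assert np.allclose(got["frac_above_0.6"], 0.0)


class TestAgreement:
    def test_majority_vote_mapping(self):
        clusters = np.array([0, 0, 1, 1, 2, 2])
        classes = np.array(["A", "A", "B", "B", "B", "A"])
        mapping = clf.map_clusters_to_classes(clusters, classes)
        assert mapping[0] == "A" and mapping[1] == "B"

    def test_unsup_vs_sup_kappa_on_blobs(self):
        X, y = _blobs(4, n_per=60, seed=7)
        labels = np.array(list("ABCD"))[y]
        model = clf.fit_kmeans(X, 4, seed=0)
        clusters = model.predict(X)
        backend = clf.train_supervised(X, labels)
        sup = backend.predict(X)
        mapping = clf.map_clusters_to_classes(clusters, sup)
        mapped = np.array([mapping[c] for c in clusters])
        assert clf.cohens_kappa(mapped.tolist(), sup.tolist()) >= 0.8


def test_evaluate_report_roundtrip():
    true = ["A", "A", "B", "B"]
    pred = ["A", "B", "B", "B"]
    proba = np.array([[0.9, 0.1], [0.4, 0.6], [0.2, 0.8], [0.1, 0.9]])
    rep = clf.evaluate(true, pred, proba, classes=["A", "B"])
    d = rep.to_dict()
    assert d["kappa"] == pytest.approx(clf.cohens_kappa(true, pred))
    assert d["fmi"] == pytest.approx(clf.fowlkes_mallows(true, pred))
    assert "f1_macro" in d and "confusion" in d and "confidence" in d
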