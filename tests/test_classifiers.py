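"""Windowed classification heads: window construction, probability contracts,
separability, and PHQ-9 per-question training."""

import numpy as np
import pytest

from moodcast.classifiers import (
    FeatureWindowSet,
    build_windows,
    combine_sources,
    predict_valence,
    train_phq9,
    train_valence,
)


def _planted(n_patients=8, T=150, K=3, w=7, seed=0, noise=0.0):
    """Planted separable signal: the label on day t is the argmax of the
    day-(t-1) K-vector, which sits at the end of the feature window."""
    rng = np.random.default_rng(seed)
    sources, labels = {}, {}
    for i in range(n_patients):
        # vectors concentrated near simplex corners, away from the argmax
        # decision boundary
        corners = rng.integers(0, K, size=T)
        dists = np.full((T, K), 0.1 / (K - 1))
        dists[np.arange(T), corners] = 0.9
        dists += rng.uniform(-0.03, 0.03, (T, K))
        dists = np.clip(dists, 1e-6, None)
        dists /= dists.sum(axis=1, keepdims=True)
        lab = np.concatenate([[np.nan], dists[:-1].argmax(axis=1).astype(float)])
        if noise:
            flip = rng.random(T) < noise
            lab[flip] = rng.integers(0, K, flip.sum())
        lab[rng.random(T) > 0.8] = np.nan
        sources[f"P{i}"] = dists
        labels[f"P{i}"] = lab
    return sources, labels


class TestBuildWindows:
    def test_feature_dimensions(self):
        rng = np.random.default_rng(0)
        src = {"a": rng.dirichlet(np.ones(7), size=30)}
        lab = {"a": np.where(rng.random(30) < 0.5, 1.0, np.nan)}
        fw = build_windows(src, lab, 7)
        assert fw.X.shape[1] == 49
        src3 = {"a": rng.dirichlet(np.ones(3), size=30)}
        fw3 = build_windows(src3, lab, 3)
        assert fw3.X.shape[1] == 9

    def test_insufficient_history_skipped(self):
        src = {"a": np.ones((10, 2))}
        lab = {"a": np.full(10, np.nan)}
        lab["a"][5] = 1.0
        fw = build_windows(src, lab, 7)
        assert len(fw.y) == 0 and fw.skipped == 1

    def test_window_never_covers_target_day(self):
        # encode the day index in the feature value and check the window max
        src = {"a": np.arange(30, dtype=float)[:, None]}
        lab = {"a": np.where(np.arange(30) % 5 == 0, 1.0, np.nan)}
        fw = build_windows(src, lab, 4)
        for row, (_, day) in zip(fw.X, fw.meta.itertuples(index=False)):
            assert row.max() == day - 1

    def test_nan_windows_skipped(self):
        src = {"a": np.vstack([np.full((5, 2), np.nan), np.ones((15, 2))])}
        lab = {"a": np.where(np.arange(20) >= 8, 1.0, np.nan)}
        fw = build_windows(src, lab, 4)
        # windows touching the NaN head (target days 8) are dropped
        assert fw.meta["day"].min() >= 9


class TestValence:
    def test_distribution_contract_and_determinism(self):
        sources, labels = _planted(noise=0.2)
        fw = build_windows(sources, labels, 7)
        clf = train_valence(fw, "XGB", seed=1)
        dist = clf.predict_distribution(fw.X[:50])
        assert np.all(dist >= 0)
        np.testing.assert_allclose(dist.sum(axis=1), 1.0, atol=1e-6)
        clf2 = train_valence(fw, "XGB", seed=1)
        np.testing.assert_array_equal(clf2.predict_distribution(fw.X[:50]), dist)

    @pytest.mark.parametrize("kind", ["XGB", "RF", "MLP"])
    def test_separable_signal_high_heldout_accuracy(self, kind):
        sources, labels = _planted(n_patients=10, seed=2)
        train = {p: labels[p] for p in list(labels)[:7]}
        test = {p: labels[p] for p in list(labels)[7:]}
        fw = build_windows(sources, train, 7)
        clf = train_valence(fw, kind, seed=0)
        held = build_windows(sources, test, 7)
        acc = (clf.predict(held.X) == held.y).mean()
        assert acc >= 0.99

    def test_macro_f1_robust_to_class_imbalance(self):
        """Separable windows remain well classified under the study's
        45.8/23.7/30.4 class imbalance."""
        from sklearn.metrics import f1_score

        rng = np.random.default_rng(3)
        weights = np.array([0.4583, 0.2374, 0.3041])
        weights = weights / weights.sum()
        sources, labels = {}, {}
        for i in range(10):
            corners = rng.choice(3, size=400, p=weights)
            dists = np.full((400, 3), 0.1)
            dists[np.arange(400), corners] = 0.8
            sources[f"P{i}"] = dists
            # label at day t is the argmax of day t-1, so windows carry the signal
            labels[f"P{i}"] = np.concatenate([[np.nan], corners[:-1].astype(float)])
        train = {p: labels[p] for p in list(labels)[:7]}
        test = {p: labels[p] for p in list(labels)[7:]}
        clf = train_valence(build_windows(sources, train, 7), "XGB", seed=0)
        held = build_windows(sources, test, 7)
        f1 = f1_score(held.y, clf.predict(held.X), average="macro")
        assert f1 >= 0.95

    def test_single_class_training_rejected(self):
        src = {"a": np.random.default_rng(0).dirichlet(np.ones(3), size=30)}
        lab = {"a": np.full(30, 1.0)}
        with pytest.raises(ValueError):
            train_valence(build_windows(src, lab, 3), "XGB", seed=0)

    def test_predict_valence_single_window(self):
        sources, labels = _planted()
        clf = train_valence(build_windows(sources, labels, 7), "XGB", seed=0)
        out = predict_valence(clf, sources["P0"][3:10])
        assert out.shape == (3,) and out.sum() == pytest.approx(1.0, abs=1e-6)

    def test_two_class_training_maps_to_three_vector(self):
        rng = np.random.default_rng(4)
        src = {"a": rng.dirichlet(np.ones(3), size=200)}
        lab = src["a"].argmax(axis=1).astype(float)
        lab[lab == 1] = 0.0  # only classes {0, 2}
        clf = train_valence(build_windows({"a": src["a"]}, {"a": lab}, 3), "XGB", seed=0)
        dist = clf.predict_distribution(src["a"][:3].reshape(1, -1) if False else build_windows({"a": src["a"]}, {"a": lab}, 3).X[:5])
        assert dist.shape == (5, 3)
        np.testing.assert_array_equal(dist[:, 1], 0.0)


class TestPHQ9:
    def test_planted_item_signal_high_auc(self):
        """An item tied to the latent regime with strong separation is
        recoverable with held-out ROC AUC >= 0.9."""
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(5)
        sources, labels = {}, {}
        for i in range(12):
            state = rng.integers(0, 2, 300)
            dists = np.column_stack([1 - state, state]) * 0.9 + 0.05
            # the item mirrors the regime of the day before the response
            item = np.concatenate([[np.nan], state[:-1].astype(float)])
            item[rng.random(300) < 0.2] = np.nan
            sources[f"P{i}"] = dists + rng.normal(0, 0.02, dists.shape)
            labels[f"P{i}"] = item
        train_ids, test_ids = list(sources)[:8], list(sources)[8:]
        fw = {9: build_windows({p: sources[p] for p in train_ids}, {p: labels[p] for p in train_ids}, 3)}
        clf = train_phq9(fw, "XGB", seed=0)
        held = build_windows({p: sources[p] for p in test_ids}, {p: labels[p] for p in test_ids}, 3)
        p1 = clf.predict_proba(9, held.X)
        assert np.all((p1 >= 0) & (p1 <= 1))
        assert roc_auc_score(held.y, p1) >= 0.9

    def test_sparse_question_skipped_with_warning(self):
        rng = np.random.default_rng(6)
        fw_ok = build_windows({"a": rng.dirichlet(np.ones(2), 100)}, {"a": rng.integers(0, 2, 100).astype(float)}, 3)
        fw_tiny = FeatureWindowSet(X=fw_ok.X[:5], y=fw_ok.y[:5], meta=fw_ok.meta[:5], window=3)
        with pytest.warns(UserWarning, match="question 2"):
            clf = train_phq9({1: fw_ok, 2: fw_tiny}, "XGB", seed=0)
        assert 1 in clf.estimators and 2 not in clf.estimators

    def test_combined_source_dimension(self):
        rng = np.random.default_rng(7)
        emb = {"a": rng.dirichlet(np.ones(7), 40)}
        emo = {"a": rng.dirichlet(np.ones(3), 40)}
        lab = {"a": np.where(rng.random(40) < 0.5, 1.0, np.nan)}
        combined = combine_sources(emb, emo, "embeddings+emotion")
        fw = build_windows(combined, lab, 5)
        assert fw.X.shape[1] == 5 * (7 + 3)
        with pytest.raises(ValueError):
            combine_sources(None, emo, "embeddings")
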