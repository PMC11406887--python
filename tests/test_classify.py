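"""PCA, thirds splitting, linear discriminant, Model/Results, ablation."""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import subspace_angles
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

import libsionome as lb
from libsionome.classify import task_labels


def rng(seed=0):
    return np.random.default_rng(seed)


class TestFitPCA:
    def test_rank_one_data_has_single_component(self):
        t = np.linspace(-1, 1, 20)
        X = 3.0 + np.outer(t, [1.0, 2.0, -1.0])
        res = lb.fit_pca(X, lb.PCAConfig(n_components=3))
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)
        assert res.explained_variance_ratio[1:] == pytest.approx(0.0, abs=1e-12)

    def test_loadings_orthonormal(self, analysis):
        res = lb.fit_pca(analysis.intensities)
        gram = res.loadings @ res.loadings.T
        np.testing.assert_allclose(gram, np.eye(res.n_components), atol=1e-8)

    def test_ratios_non_increasing_and_bounded(self, analysis):
        res = lb.fit_pca(analysis.intensities)
        evr = res.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12)
        assert np.all(evr >= 0) and evr.sum() <= 1 + 1e-9

    def test_full_rank_ratios_sum_to_one(self):
        X = rng(3).normal(size=(12, 6))
        res = lb.fit_pca(X, lb.PCAConfig(n_components=6))
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-8)

    def test_planted_two_factor_subspace_recovered(self):
        # zero-noise rank-2 data: top-2 loadings span the planted subspace
        u = np.array([1.0, 0.0, 1.0, 0.0, 1.0]) / np.sqrt(3)
        v = np.array([0.0, 1.0, 0.0, -1.0, 0.0]) / np.sqrt(2)
        g = rng(1)
        X = 5.0 + np.outer(g.normal(size=40) * 3, u) + np.outer(g.normal(size=40), v)
        res = lb.fit_pca(X, lb.PCAConfig(n_components=2))
        angles = subspace_angles(res.loadings.T, np.column_stack([u, v]))
        assert np.max(angles) < 1e-6

    def test_sign_convention_deterministic(self):
        X = rng(2).normal(size=(15, 4))
        res = lb.fit_pca(X, lb.PCAConfig(n_components=3))
        for k in range(3):
            j = np.argmax(np.abs(res.loadings[k]))
            assert res.loadings[k, j] > 0

    def test_excessive_components_rejected(self):
        X = rng(0).normal(size=(5, 3))
        with pytest.raises(ValueError, match="n_components"):
            lb.fit_pca(X, lb.PCAConfig(n_components=5))

    def test_nonfinite_rejected(self):
        X = np.array([[1.0, np.nan], [2.0, 3.0], [0.0, 1.0]])
        with pytest.raises(ValueError, match="non-finite"):
            lb.fit_pca(X, lb.PCAConfig(n_components=1))


class TestSplitThirds:
    def test_four_classes_of_twenty(self):
        labels = np.repeat(["a", "b", "c", "d"], 20)
        train, test = lb.split_thirds(labels, lb.SplitConfig(seed=0))
        assert train.size == 28 and test.size == 52  # round(20/3)=7 per class
        for cls in "abcd":
            assert np.sum(labels[train] == cls) == 7

    def test_minimal_class_of_three(self):
        train, test = lb.split_thirds(["x", "x", "x"], lb.SplitConfig(seed=5))
        assert train.size == 1 and test.size == 2

    def test_seed_reproducibility(self):
        labels = np.repeat(["a", "b"], 15)
        s1 = lb.split_thirds(labels, lb.SplitConfig(seed=9))
        s2 = lb.split_thirds(labels, lb.SplitConfig(seed=9))
        np.testing.assert_array_equal(s1[0], s2[0])
        np.testing.assert_array_equal(s1[1], s2[1])

    def test_disjoint_and_exhaustive(self):
        labels = np.repeat(["a", "b", "c"], 11)
        train, test = lb.split_thirds(labels, lb.SplitConfig(seed=2))
        assert np.intersect1d(train, test).size == 0
        np.testing.assert_array_equal(np.sort(np.concatenate([train, test])),
                                      np.arange(labels.size))

    def test_small_class_rejected_when_stratified(self):
        with pytest.raises(ValueError, match="at least 3"):
            lb.split_thirds(["a", "a", "a", "b", "b"], lb.SplitConfig(seed=0))

    def test_unstratified_split(self):
        labels = np.repeat(["a", "b"], 15)
        train, test = lb.split_thirds(labels, lb.SplitConfig(seed=1, stratified=False))
        assert train.size == 10 and test.size == 20


class TestLinearClassifier:
    def test_one_dimensional_boundary_at_midpoint(self):
        # equal-covariance discriminant: boundary at the mean of class means
        X = np.array([[0.0], [0.4], [-0.4], [4.0], [3.6], [4.4]])
        y = np.array(["lo", "lo", "lo", "hi", "hi", "hi"])
        clf = lb.train_linear_classifier(X, y)
        assert clf.predict(np.array([[1.99]]))[0] == "lo"
        assert clf.predict(np.array([[2.01]]))[0] == "hi"

    def test_separated_classes_trained_perfectly(self):
        g = rng(4)
        X = np.vstack([g.normal(0, 0.1, (20, 3)), g.normal(5, 0.1, (20, 3))])
        y = np.repeat(["a", "b"], 20)
        clf = lb.train_linear_classifier(X, y)
        assert np.mean(clf.predict(X) == y) == 1.0

    def test_matches_sklearn_lda(self):
        # independent cross-check against sklearn's LDA with uniform priors
        g = rng(7)
        X = np.vstack([
            g.normal([0, 0], 1.0, (30, 2)),
            g.normal([2.0, 1.0], 1.0, (30, 2)),
            g.normal([-1.0, 2.5], 1.0, (30, 2)),
        ])
        y = np.repeat(["a", "b", "c"], 30)
        ours = lb.train_linear_classifier(X, y)
        ref = LinearDiscriminantAnalysis(priors=[1 / 3] * 3, solver="lsqr").fit(X, y)
        grid = g.normal(0.5, 2.0, (200, 2))
        agreement = np.mean(ours.predict(grid) == ref.predict(grid))
        assert agreement > 0.99

    def test_degenerate_covariance_falls_back_to_nearest_mean(self):
        X = np.array([[0.0, 0.0]] * 3 + [[1.0, 1.0]] * 3)
        y = np.repeat(["a", "b"], 3)
        clf = lb.train_linear_classifier(X, y)
        assert clf.regularized
        assert clf.predict(np.array([[0.1, 0.1], [0.9, 0.9]])).tolist() == ["a", "b"]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            lb.train_linear_classifier(np.zeros((4, 2)), ["a"] * 4)

    def test_rotation_invariance(self, analysis):
        scores = lb.fit_pca(analysis.intensities).scores.to_numpy()
        labels = task_labels(analysis.meta, "combined")
        train, test = lb.split_thirds(labels, lb.SplitConfig(seed=1))
        q, _ = np.linalg.qr(rng(11).normal(size=(scores.shape[1],) * 2))
        acc, acc_rot = [], []
        for S in (scores, scores @ q):
            clf = lb.train_linear_classifier(S[train], labels[train])
            rep = lb.evaluate(clf, S[test], labels[test])
            acc.append(rep.accuracy)
        assert acc[0] == pytest.approx(acc[1], abs=1e-12)


class TestEvaluate:
    def test_perfect_predictions(self):
        X = np.array([[0.0], [10.0]])
        clf = lb.train_linear_classifier(
            np.array([[0.0], [0.2], [10.0], [10.2]]), ["a", "a", "b", "b"]
        )
        rep = lb.evaluate(clf, X, ["a", "b"])
        assert rep.accuracy == 1.0
        assert rep.confusion.loc["a", "a"] == 1
        assert rep.confusion.loc["b", "b"] == 1
        assert len(rep.misclassified) == 0

    def test_all_wrong_binary(self):
        clf = lb.train_linear_classifier(
            np.array([[0.0], [0.2], [10.0], [10.2]]), ["a", "a", "b", "b"]
        )
        rep = lb.evaluate(clf, np.array([[10.0], [0.0]]), ["a", "b"])
        assert rep.accuracy == 0.0

    def test_unseen_class_flagged(self):
        clf = lb.train_linear_classifier(
            np.array([[0.0], [0.2], [10.0], [10.2]]), ["a", "a", "b", "b"]
        )
        rep = lb.evaluate(clf, np.array([[0.1], [5.0]]), ["a", "z"])
        assert rep.unseen_classes == ["z"]
        assert "z" in rep.confusion.index

    def test_accuracy_equals_confusion_trace(self, analysis):
        res = lb.SpectralClassificationModel(
            analysis, task="combined", split_config=lb.SplitConfig(seed=1)
        ).fit()
        conf = res.confusion
        diag = sum(conf.loc[c, c] for c in conf.columns if c in conf.index)
        assert res.accuracy == pytest.approx(diag / conf.to_numpy().sum())


class TestModelResults:
    def test_summary_reports_task_and_accuracy(self, analysis):
        res = lb.SpectralClassificationModel(
            analysis, task="species", split_config=lb.SplitConfig(seed=1)
        ).fit()
        text = res.summary()
        assert "species" in text
        assert "test accuracy" in text
        assert f"{res.accuracy * 100:.1f}%" in text

    def test_from_shots_runs_full_chain(self, tiny_shots):
        res = lb.SpectralClassificationModel.from_shots(
            tiny_shots, task="media", split_config=lb.SplitConfig(seed=0)
        ).fit()
        assert res.report.n_train + res.report.n_test == 16

    def test_intensity_table_mode(self, intensity_table):
        model = lb.SpectralClassificationModel(
            intensity_table, task="media",
            pca_config=lb.PCAConfig(n_components=5, input_mode="intensity_table"),
            split_config=lb.SplitConfig(seed=1),
        )
        res = model.fit()
        assert 0.0 <= res.accuracy <= 1.0

    def test_unknown_task_rejected(self, analysis):
        with pytest.raises(ValueError, match="task"):
            lb.SpectralClassificationModel(analysis, task="strain")


class TestAveragingAblation:
    def test_k8_halves_spectrum_count(self, default_shots):
        out = lb.averaging_ablation(
            default_shots, k_values=(4, 8), split_config=lb.SplitConfig(seed=1)
        )
        n4 = out[4].report.n_train + out[4].report.n_test
        n8 = out[8].report.n_train + out[8].report.n_test
        assert (n4, n8) == (80, 40)

    def test_zero_noise_perfect_at_every_k(self, noiseless_shots):
        out = lb.averaging_ablation(
            noiseless_shots, k_values=(4, 8), split_config=lb.SplitConfig(seed=0)
        )
        assert out[4].accuracy == 1.0
        assert out[8].accuracy == 1.0

    def test_more_averaging_does_not_hurt_on_average(self):
        # noise-variance reduction: mean accuracy(k=8) >= mean accuracy(k=4),
        # checked at a planted fold small enough that k=4 is not saturated
        acc4, acc8 = [], []
        for seed in range(1, 11):
            shots = lb.generate_study(
                lb.paper_n80(seed=seed),
                effects=lb.default_effect_directions(effect_size=1.3),
            )
            out = lb.averaging_ablation(
                shots, k_values=(4, 8), split_config=lb.SplitConfig(seed=seed)
            )
            acc4.append(out[4].accuracy)
            acc8.append(out[8].accuracy)
        assert np.mean(acc8) >= np.mean(acc4) - 1e-9


class TestParameterRecovery:
    def test_single_factor_tasks_reach_full_accuracy_in_most_runs(self):
        # media and species tasks hit 100% test accuracy in >=95% of 20 runs
        hits = {"media": 0, "species": 0}
        for seed in range(1, 21):
            analysis = lb.preprocess(lb.generate_study(lb.paper_n80(seed=seed)))
            for task in hits:
                res = lb.SpectralClassificationModel(
                    analysis, task=task, split_config=lb.SplitConfig(seed=seed)
                ).fit()
                hits[task] += res.accuracy == 1.0
        assert hits["media"] >= 19
        assert hits["species"] >= 19

    def test_larger_effect_size_does_not_reduce_accuracy(self):
        # monotonicity in the planted fold change, averaged over 10 seeds
        means = {}
        for fold in (1.2, 2.0):
            accs = []
            for seed in range(1, 11):
                shots = lb.generate_study(
                    lb.paper_n80(seed=seed),
                    effects=lb.default_effect_directions(effect_size=fold),
                )
                res = lb.SpectralClassificationModel.from_shots(
                    shots, task="combined", split_config=lb.SplitConfig(seed=seed)
                ).fit()
                accs.append(res.accuracy)
            means[fold] = np.mean(accs)
        assert means[2.0] >= means[1.2] - 1e-9
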