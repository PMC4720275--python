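"""Feature building, one-vs-one SVM, repeated CV, permutation test."""


import numpy as np
import pytest

import tonocortex as tc
from tonocortex.preprocess import EpochSet
from tonocortex.protocol import StimulusType


def _toy_fm(X, y, names=None):
    y = np.asarray(y)
    names = names if names is not None else sorted(set(y.tolist()))
    return tc.FeatureMatrix(X=np.asarray(X, float), y=y,
                            class_names=list(names), feature_layout=(1, X.shape[1]))


class TestFeatureMatrix:
    def test_frequency_task_shape(self, effect_dataset):
        fm = tc.build_feature_matrix(effect_dataset.epochs, "frequency",
                                     modality="binaural")
        # 4 frequencies x 40 trials; 16 channels x 350 poststimulus samples
        assert fm.X.shape == (160, 16 * 350)
        assert fm.n_classes == 4 and fm.chance_level == 0.25
        assert np.bincount(fm.y).tolist() == [40, 40, 40, 40]

    def test_feature_layout_channel_major(self, effect_dataset):
        ep = effect_dataset.epochs
        fm = tc.build_feature_matrix(ep, "frequency", modality="left")
        trial = next(i for i, l in enumerate(ep.labels) if l.modality == "left")
        tmask = (ep.time_axis_ms >= 0) & (ep.time_axis_ms < 350)
        # row 0 of X is the first left-modality trial; channel 1's block
        # follows channel 0's 350 samples
        row = fm.X[0]
        np.testing.assert_array_equal(row[:350], ep.data[trial, 0, tmask])
        np.testing.assert_array_equal(row[350:700], ep.data[trial, 1, tmask])

    def test_modality_task(self, effect_dataset):
        fm = tc.build_feature_matrix(effect_dataset.epochs, "modality")
        assert fm.n_classes == 3 and fm.chance_level == pytest.approx(1 / 3)
        assert fm.X.shape[0] == 480

    def test_errors(self, effect_dataset):
        with pytest.raises(ValueError, match="needs a modality"):
            tc.build_feature_matrix(effect_dataset.epochs, "frequency")
        ep = effect_dataset.epochs
        only_left = EpochSet(
            data=ep.data[:2], time_axis_ms=ep.time_axis_ms,
            channel_labels=ep.channel_labels,
            labels=[StimulusType(250, "left"), StimulusType(500, "left")])
        with pytest.raises(ValueError, match=">= n_folds"):
            tc.build_feature_matrix(only_left, "frequency", modality="left")


class TestSVM:
    def test_separable_toy_and_brute_force_boundary(self):
        """4-point margin-obvious toy set; sign checked against exhaustive
        grid search for the max-margin separator."""
        X = np.array([[-2.0, 0.0], [-1.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        y = np.array([0, 0, 1, 1])
        pred = tc.svm_ovo_fit_predict(X, y, X)
        np.testing.assert_array_equal(pred, y)
        # brute force: best separator w x + b over a coarse grid
        best, best_margin = None, -np.inf
        for w in np.linspace(-2, 2, 81):
            for b in np.linspace(-2, 2, 81):
                if w == 0:
                    continue
                s = np.sign(w * X[:, 0] + b)
                if np.all(s == np.where(y == 0, -1, 1)):
                    margin = np.min(np.abs(w * X[:, 0] + b)) / abs(w)
                    if margin > best_margin:
                        best, best_margin = (w, b), margin
        w, b = best
        tests = np.array([[-0.5, 0.0], [0.5, 0.0], [-3.0, 1.0], [3.0, -1.0]])
        svm_pred = tc.svm_ovo_fit_predict(X, y, tests)
        brute_pred = (w * tests[:, 0] + b > 0).astype(int)
        np.testing.assert_array_equal(svm_pred, brute_pred)

    def test_training_point_label_preserved(self):
        X = np.array([[0.0, 1.0], [0.0, 2.0], [3.0, 0.0], [4.0, 0.0]])
        y = np.array([0, 0, 1, 1])
        assert tc.svm_ovo_fit_predict(X, y, X[1:2])[0] == 0

    def test_four_class_orthogonal_means(self, rng):
        """Orthogonal class means at SNR 5: accuracy >> chance."""
        n_per, d = 30, 8
        means = np.zeros((4, d))
        for k in range(4):
            means[k, k] = 5.0
        X = np.vstack([means[k] + rng.standard_normal((n_per, d))
                       for k in range(4)])
        y = np.repeat(np.arange(4), n_per)
        perm = rng.permutation(len(y))
        train, test = perm[:80], perm[80:]
        pred = tc.svm_ovo_fit_predict(X[train], y[train], X[test])
        assert np.mean(pred == y[test]) > 0.9

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="2 classes"):
            tc.svm_ovo_fit_predict(np.zeros((3, 2)), np.zeros(3, int),
                                   np.zeros((1, 2)))


class TestCrossValidation:
    def test_one_hot_features_give_perfect_accuracy(self):
        y = np.repeat(np.arange(4), 12)
        X = np.eye(4)[y] * 10.0
        fm = _toy_fm(X, y)
        acc, per_class, _, _ = tc.cross_validated_accuracy(
            fm, tc.CVConfig(n_repetitions=5, seed=0))
        assert acc == 1.0
        assert all(v == 1.0 for v in per_class.values())

    def test_fold_partition_property(self):
        """Each retained trial appears in exactly one test fold per repetition.

        The split is a permutation truncated to a multiple of k and reshaped,
        so the k groups are equal-sized, disjoint, and cover the retained
        trials; verified here for n mod k != 0.
        """
        n, k = 37, 4                          # n mod k = 1 dropped
        r = np.random.default_rng(5)
        perm = r.permutation(n)
        usable = n - (n % k)
        folds = perm[:usable].reshape(k, usable // k)
        flat = np.concatenate(folds)
        assert len(flat) == usable
        assert len(np.unique(flat)) == usable   # disjoint cover
        assert {len(f) for f in folds} == {usable // k}

    def test_null_labels_converge_to_chance(self, rng):
        """Label-shuffled accuracy approaches 1/K with growing n (K = 3, 4).

        Small samples sit slightly *below* chance: a test fold that
        over-represents a class under-represents it in training, biasing the
        classifier against it (the known below-chance artifact of random
        equal-size splits).  The bias must shrink as trials grow.
        """
        for K in (3, 4):
            devs = []
            for n_per in (16, 96):
                y = np.repeat(np.arange(K), n_per)
                X = rng.standard_normal((len(y), 10))
                fm = _toy_fm(X, y)
                acc, _, accs, _ = tc.cross_validated_accuracy(
                    fm, tc.CVConfig(n_repetitions=10, seed=K))
                devs.append(acc - 1 / K)
            assert abs(devs[1]) < 0.05              # near chance at large n
            assert devs[1] >= devs[0] - 0.02        # bias shrinks with n

    def test_determinism(self, rng):
        y = np.repeat(np.arange(4), 10)
        X = rng.standard_normal((40, 6))
        fm = _toy_fm(X, y)
        cfg = tc.CVConfig(n_repetitions=7, seed=11)
        a = tc.cross_validated_accuracy(fm, cfg)
        b = tc.cross_validated_accuracy(fm, cfg)
        assert a[0] == b[0]
        np.testing.assert_array_equal(a[2], b[2])


class TestPermutation:
    def test_perfect_separation_gives_p_zero(self):
        y = np.repeat(np.arange(4), 12)
        X = np.eye(4)[y] * 10.0
        fm = _toy_fm(X, y)
        cfg = tc.CVConfig(n_repetitions=2, n_permutations=200, seed=0)
        acc, per_class, _, _ = tc.cross_validated_accuracy(fm, cfg)
        p, p_pc, null = tc.permutation_pvalue(fm, acc, cfg, per_class)
        assert p == 0.0
        assert null.max() < 1.0

    def test_observed_below_null_median_gives_large_p(self, rng):
        y = np.repeat(np.arange(4), 10)
        X = rng.standard_normal((40, 5))
        fm = _toy_fm(X, y)
        cfg = tc.CVConfig(n_repetitions=1, n_permutations=60, seed=2)
        # observed accuracy 0.0 sits below every null draw
        p, _, null = tc.permutation_pvalue(fm, 0.0, cfg)
        assert p > 0.5
        assert p == np.mean(null >= 0.0) == 1.0

    def test_null_pvalue_calibration(self, rng):
        """Over null datasets the permutation p rejects at ~ nominal rate."""
        hits, n_data = 0, 40
        for i in range(n_data):
            y = np.repeat(np.arange(4), 8)
            X = rng.standard_normal((len(y), 6))
            fm = _toy_fm(X, y)
            cfg = tc.CVConfig(n_repetitions=2, n_permutations=40, seed=100 + i)
            acc, _, _, _ = tc.cross_validated_accuracy(fm, cfg)
            p, _, _ = tc.permutation_pvalue(fm, acc, cfg)
            hits += p < 0.05
        assert hits / n_data <= 0.15          # no gross anti-conservatism


class TestSuite:
    def test_suite_runs_all_tasks_and_records_failures(self, effect_dataset):
        cfg = tc.CVConfig(n_repetitions=2, n_permutations=5, seed=0)
        out = tc.run_classification_suite(effect_dataset.epochs, cfg)
        assert set(out) == {"modality", "frequency:left", "frequency:right",
                            "frequency:binaural"}
        for oc in out.values():
            assert oc.error is None
            assert 0 <= oc.global_accuracy <= 1
        # epochs missing one modality: that task fails, the others survive
        ep = effect_dataset.epochs
        keep = [i for i, l in enumerate(ep.labels) if l.modality != "left"]
        partial = EpochSet(data=ep.data[keep], time_axis_ms=ep.time_axis_ms,
                           channel_labels=ep.channel_labels,
                           labels=[ep.labels[i] for i in keep])
        out = tc.run_classification_suite(partial, cfg)
        assert out["frequency:left"].error is not None
        assert out["frequency:binaural"].error is None
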