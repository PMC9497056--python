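"""Split protocols, scaling, t-test selection, and the two classifier tracks."""

import hashlib

import numpy as np
import pandas as pd
import pytest

from epiclass import (FeatureTable, GBDTParams, SelectionError, SplitError,
                      SplitSpec, SVMGrid, apply_scaler, fit_scaler, predict,
                      roc_auc, stratified_split, train_gbdt, train_svm,
                      ttest_select)


def _table(X, y, subjects=None):
    frame = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
    frame.insert(0, "label", y)
    frame.insert(0, "subject_id", subjects or [f"S{i}" for i in range(len(y))])
    frame.insert(0, "recording_id", [f"R{i}" for i in range(len(y))])
    return FeatureTable(frame=frame)


def _blobs(n_pos=40, n_neg=40, gap=6.0, seed=0, n_features=4):
    rng = np.random.default_rng(seed)
    Xp = rng.standard_normal((n_pos, n_features)) + gap
    Xn = rng.standard_normal((n_neg, n_features))
    X = np.vstack([Xp, Xn])
    y = np.array([1] * n_pos + [0] * n_neg)
    perm = rng.permutation(len(y))
    return _table(X[perm], y[perm])


@pytest.fixture(scope="module")
def corpus_like_table():
    """75 positive / 30 negative rows, mildly informative features."""
    rng = np.random.default_rng(7)
    y = np.array([1] * 75 + [0] * 30)
    X = rng.standard_normal((105, 6)) + 1.5 * y[:, None]
    return _table(X, y)


class TestStratifiedSplit:
    def test_seven_three_split_of_corpus(self, corpus_like_table):
        train, test = stratified_split(corpus_like_table, SplitSpec(0.7, True, 0))
        assert len(train) in (73, 74)
        assert int(train.labels.sum()) in (52, 53)
        assert len(train) + len(test) == 105

    def test_eight_two_split_test_size(self, corpus_like_table):
        train, test = stratified_split(corpus_like_table, SplitSpec(0.8, True, 1))
        assert len(test) == 21
        # class proportions preserved within one sample per class
        assert abs(test.labels.sum() - 0.2 * 75) <= 1

    def test_same_seed_same_partition(self, corpus_like_table):
        a = stratified_split(corpus_like_table, SplitSpec(0.7, True, 5))
        b = stratified_split(corpus_like_table, SplitSpec(0.7, True, 5))
        for ta, tb in zip(a, b):
            pd.testing.assert_frame_equal(ta.frame, tb.frame)

    def test_partition_is_disjoint_and_exhaustive(self, corpus_like_table):
        train, test = stratified_split(corpus_like_table, SplitSpec(0.7, True, 3))
        ids = set(train.frame.recording_id) | set(test.frame.recording_id)
        assert len(ids) == 105
        assert not set(train.frame.recording_id) & set(test.frame.recording_id)

    def test_single_class_rejected(self):
        t = _table(np.random.default_rng(0).standard_normal((10, 2)),
                   np.ones(10, dtype=int))
        with pytest.raises(SplitError):
            stratified_split(t, SplitSpec(0.7, True, 0))

    def test_subject_level_split_keeps_subjects_intact(self):
        rng = np.random.default_rng(13)
        y = np.repeat([1] * 6 + [0] * 4, 3)  # 10 subjects x 3 recordings
        subjects = [f"P{i // 3}" for i in range(30)]
        t = _table(rng.standard_normal((30, 2)), y, subjects=subjects)
        train, test = stratified_split(
            t, SplitSpec(0.7, True, 0, unit="subject"))
        overlap = set(train.frame.subject_id) & set(test.frame.subject_id)
        assert not overlap
        assert len(train) + len(test) == 30
        # subject-level stratification: both classes in both parts
        assert len(set(train.labels)) == 2 and len(set(test.labels)) == 2


class TestScaler:
    def test_training_rows_become_standard(self, rng):
        X = rng.standard_normal((50, 5)) * 7 + 3
        params = fit_scaler(X, [f"f{i}" for i in range(5)])
        Xs = apply_scaler(X, params)
        np.testing.assert_allclose(Xs.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(Xs.std(axis=0), 1.0, atol=1e-9)

    def test_constant_feature_warns_and_zeroes(self, rng):
        X = rng.standard_normal((20, 2))
        X[:, 1] = 4.2
        with pytest.warns(UserWarning, match="zero-variance"):
            params = fit_scaler(X, ["a", "b"])
        Xs = apply_scaler(X, params)
        np.testing.assert_allclose(Xs[:, 1], 0.0, atol=1e-12)

    def test_test_rows_use_training_statistics(self, rng):
        X = rng.standard_normal((30, 3)) * 2 + 5
        params = fit_scaler(X, ["a", "b", "c"])
        row = X.mean(axis=0, keepdims=True)
        np.testing.assert_allclose(apply_scaler(row, params), 0.0, atol=1e-9)


class TestTTestSelect:
    def test_label_copy_feature_retained(self, rng):
        y = np.array([0, 1] * 20)
        X = np.column_stack([y + 0.01 * rng.standard_normal(40),
                             rng.standard_normal(40)])
        mask = ttest_select(X, y, ["signal", "noise"], alpha=0.05)
        assert mask.keep[0]

    def test_null_feature_retention_rate_near_alpha(self):
        """Pure-noise features survive at roughly the type-I error rate."""
        rng = np.random.default_rng(99)
        y = np.array([0] * 20 + [1] * 20)
        kept = 0
        n_total = 0
        for _ in range(200):
            X = rng.standard_normal((40, 5))
            mask = ttest_select(X, y, list("abcde"), alpha=0.05)
            # ignore the fallback feature when nothing is significant
            if mask.p_value.min() < 0.05:
                kept += int(mask.keep.sum())
            n_total += 5
        assert 0.02 < kept / n_total < 0.09

    def test_all_noise_fallback_keeps_single_best(self):
        rng = np.random.default_rng(3)
        y = np.array([0] * 10 + [1] * 10)
        for _ in range(20):
            X = rng.standard_normal((20, 4))
            mask = ttest_select(X, y, list("abcd"), alpha=1e-9)
            assert mask.keep.sum() == 1
            assert mask.keep[np.argmin(mask.p_value)]

    def test_single_class_rejected(self, rng):
        with pytest.raises(SelectionError):
            ttest_select(rng.standard_normal((10, 2)), np.ones(10), ["a", "b"])


class TestTrainSVM:
    def test_grid_enumerates_81_pairs(self):
        table = _blobs(seed=1)
        handle = train_svm(table, SVMGrid(), seed=0)
        assert len(handle.cv_table) == 81
        assert set(handle.cv_table.C_exponent) == set(range(-4, 5))
        assert set(handle.cv_table.gamma_exponent) == set(range(-4, 5))

    def test_best_pair_is_cv_argmax_under_tie_rule(self):
        table = _blobs(seed=2)
        handle = train_svm(table, seed=0)
        cv = handle.cv_table
        best_acc = cv.cv_accuracy.max()
        ties = cv[cv.cv_accuracy == best_acc].sort_values(["C", "gamma"])
        assert handle.hyperparameters["C"] == ties.iloc[0]["C"]
        assert handle.hyperparameters["gamma"] == ties.iloc[0]["gamma"]

    def test_separable_blobs_classified(self):
        train_tab = _blobs(seed=3)
        test_tab = _blobs(seed=4)
        handle = train_svm(train_tab, seed=0)
        pred_tr, _ = predict(handle, train_tab)
        assert np.mean(pred_tr == train_tab.labels) == 1.0
        pred_te, _ = predict(handle, test_tab)
        assert np.mean(pred_te == test_tab.labels) >= 0.95

    def test_shuffled_labels_give_chance_level_cv(self):
        rng = np.random.default_rng(11)
        accs = []
        for s in range(5):
            table = _blobs(n_pos=30, n_neg=30, seed=s)
            shuffled = table.frame.copy()
            shuffled["label"] = rng.permutation(shuffled["label"].to_numpy())
            handle = train_svm(FeatureTable(shuffled), seed=s)
            accs.append(handle.hyperparameters["cv_accuracy"])
        # majority rate is 0.5; optimistic selection bias stays modest
        assert 0.4 <= np.mean(accs) <= 0.72


class TestTrainGBDT:
    def test_separable_blobs_classified(self):
        handle = train_gbdt(_blobs(seed=5), seed=0)
        test_tab = _blobs(seed=6)
        pred, _ = predict(handle, test_tab)
        assert np.mean(pred == test_tab.labels) >= 0.95

    def test_single_informative_feature_is_enough(self):
        y = np.array([0, 1] * 30)
        X = y[:, None].astype(float)
        table = _table(X, y)
        handle = train_gbdt(table, seed=0)
        pred, _ = predict(handle, table)
        np.testing.assert_array_equal(pred, y)

    def test_cv_grid_covers_declared_candidates(self):
        handle = train_gbdt(_blobs(seed=7), GBDTParams(), seed=0)
        assert len(handle.cv_table) == 6
        assert set(handle.cv_table.n_estimators) == {50, 100, 200}
        assert set(handle.cv_table.max_depth) == {2, 3}


class TestPredict:
    def test_empty_rows_give_empty_outputs(self):
        table = _blobs(seed=8)
        handle = train_svm(table, seed=0)
        empty = FeatureTable(table.frame.iloc[0:0])
        labels, scores = predict(handle, empty)
        assert labels.size == 0 and scores.size == 0

    def test_missing_feature_is_a_contract_error(self):
        from epiclass import ContractError

        table = _blobs(seed=9)
        handle = train_svm(table, seed=0)
        broken = FeatureTable(table.frame.drop(columns=["f0"]))
        with pytest.raises(ContractError, match="f0"):
            predict(handle, broken)

    def test_scores_monotone_in_positive_feature(self):
        """GBDT score never decreases when a label-aligned feature rises."""
        y = np.array([0, 1] * 40)
        rng = np.random.default_rng(21)
        X = np.column_stack([y * 2.0 + 0.05 * rng.standard_normal(80)])
        handle = train_gbdt(_table(X, y), seed=0)
        grid = np.linspace(-1, 3, 30)[:, None]
        probe = _table(grid, np.zeros(30, dtype=int))
        _, scores = predict(handle, probe)
        assert np.all(np.diff(scores) >= -1e-12)


class TestNoLeakage:
    def test_preprocessing_statistics_ignore_test_rows(self, corpus_like_table):
        """Perturbing test rows must not move scaler/selection parameters."""
        train, test = stratified_split(corpus_like_table, SplitSpec(0.8, True, 0))

        def checksum(handle):
            mask_bytes = (handle.mask.keep.tobytes() +
                          handle.mask.p_value.tobytes())
            return hashlib.sha256(handle.scaler.mean.tobytes()
                                  + handle.scaler.scale.tobytes()
                                  + mask_bytes).hexdigest()

        h1 = train_gbdt(train, seed=0)
        # mutate the test rows wildly; retrain on the identical train rows
        test.frame.iloc[:, 3:] += 1e6
        h2 = train_gbdt(train, seed=0)
        assert checksum(h1) == checksum(h2)
        assert h1.hyperparameters == h2.hyperparameters


class TestPermutationSanity:
    def test_label_shuffle_auc_near_chance(self, corpus_like_table):
        """Pooled-CV AUC under label shuffling stays in the null band."""
        from epiclass import cv_pooled_scores

        rng = np.random.default_rng(5)
        in_band = 0
        n_seeds = 3
        for s in range(n_seeds):
            shuffled = corpus_like_table.frame.copy()
            shuffled["label"] = rng.permutation(shuffled["label"].to_numpy())
            t = FeatureTable(shuffled)
            y, scores, _ = cv_pooled_scores(t, "GBDT", seed=s)
            _, auc = roc_auc(scores, y)
            if 0.35 <= auc <= 0.65:
                in_band += 1
        assert in_band >= n_seeds - 1
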