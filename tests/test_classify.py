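"""Labelling, folds, undersampling, tuning and the full protocol."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_gaussian_trials, make_labeled_set
from windeeg.classify import (
    FAMILIES,
    AnnClassifier,
    ClassifierSpec,
    build_estimator,
    label_and_filter,
    make_velocity_folds,
    normalize_features,
    run_protocol,
    sample_config,
    train_and_test,
    tune_hyperparameters,
    undersample_training,
)
from windeeg.exceptions import InvalidParameterError, NumericalError
from windeeg.features import FEATURE_COLUMNS


def _feature_table(scores, velocities=None):
    n = len(scores)
    rng = np.random.default_rng(0)
    table = pd.DataFrame(
        rng.standard_normal((n, 24)), columns=list(FEATURE_COLUMNS)
    )
    table["score"] = scores
    table["velocity"] = (
        velocities if velocities is not None else np.tile([0.44, 1.0, 2.0, 4.0], n)[:n]
    )
    table["session"] = 0
    table["trial"] = np.arange(n)
    return table


class TestLabelAndFilter:
    def test_label_rule_and_neutral_dropped(self):
        table = _feature_table([6.9, 4.3, 5.0, 7.7, 2.1])
        labeled, _ = label_and_filter(table, min_per_class=1)
        assert labeled.n_trials == 4  # the 5.0 report is gone
        np.testing.assert_array_equal(labeled.labels, [1, 0, 1, 0])

    def test_exclusion_rule(self):
        scores = np.concatenate([np.full(25, 3.0), np.full(95, 7.0)])
        _, included = label_and_filter(_feature_table(scores))
        assert not included
        scores = np.concatenate([np.full(30, 3.0), np.full(90, 7.0)])
        _, included = label_and_filter(_feature_table(scores))
        assert included

    def test_out_of_scale_scores_rejected(self):
        with pytest.raises(InvalidParameterError):
            label_and_filter(_feature_table([0.5, 6.0, 7.0, 8.0]))


class TestVelocityFolds:
    def test_each_velocity_tested_once(self):
        labeled = make_labeled_set(seed=0)
        folds = make_velocity_folds(labeled, min_per_class=1)
        assert sorted(f.test_velocity for f in folds) == [0.44, 1.0, 2.0, 4.0]
        for f in folds:
            assert f.test_velocity not in f.train_velocities
            assert len(f.train_velocities) == 3

    def test_quoted_example_fold(self):
        labeled = make_labeled_set(seed=0)
        folds = make_velocity_folds(labeled, min_per_class=1)
        f044 = next(f for f in folds if f.test_velocity == 0.44)
        assert f044.train_velocities == (1.0, 2.0, 4.0)

    def test_sparse_training_class_marks_infeasible(self):
        labeled = make_labeled_set(n_trials=160, seed=1)
        # 29 unpleasant in the training partition of one fold -> infeasible
        folds = make_velocity_folds(labeled, min_per_class=10**6)
        assert all(not f.feasible and f.reason for f in folds)

    def test_missing_velocity_rejected(self):
        labeled = make_labeled_set(seed=2)
        labeled.velocities[:] = 1.0
        with pytest.raises(InvalidParameterError):
            make_velocity_folds(labeled)


class TestUndersampling:
    def test_balances_to_minority_count(self):
        rng = np.random.default_rng(0)
        labels = np.concatenate([np.zeros(33, int), np.ones(47, int)])
        idx = np.arange(80)
        balanced = undersample_training(idx, labels, rng)
        y = labels[balanced]
        assert (y == 0).sum() == (y == 1).sum() == 33

    def test_equal_counts_identity(self):
        rng = np.random.default_rng(0)
        labels = np.concatenate([np.zeros(10, int), np.ones(10, int)])
        idx = np.arange(20)
        np.testing.assert_array_equal(undersample_training(idx, labels, rng), idx)

    def test_repetitions_discard_distinct_subsets(self):
        rng = np.random.default_rng(0)
        labels = np.concatenate([np.zeros(33, int), np.ones(40, int)])
        idx = np.arange(73)
        used: set = set()
        draws = [
            frozenset(idx) - frozenset(undersample_training(idx, labels, rng, used))
            for _ in range(5)
        ]
        assert len(set(draws)) == 5

    def test_empty_class_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(InvalidParameterError):
            undersample_training(np.arange(5), np.zeros(5, int), rng)


class TestNormalization:
    def test_training_statistics_and_no_leakage(self):
        rng = np.random.default_rng(0)
        train = rng.normal(5.0, 3.0, size=(50, 24))
        test = rng.normal(9.0, 3.0, size=(20, 24))
        tr, te = normalize_features(train, test)
        np.testing.assert_allclose(tr.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(tr.std(axis=0), 1.0, atol=1e-10)
        assert np.abs(te.mean(axis=0)).min() > 0.5  # test stats untouched

    def test_shift_invariance(self):
        rng = np.random.default_rng(1)
        train = rng.standard_normal((30, 4))
        test = rng.standard_normal((10, 4))
        tr1, te1 = normalize_features(train, test)
        tr2, te2 = normalize_features(train + 100.0, test + 100.0)
        np.testing.assert_allclose(tr1, tr2, atol=1e-8)
        np.testing.assert_allclose(te1, te2, atol=1e-8)

    def test_zero_variance_column_named(self):
        train = np.ones((10, 3))
        with pytest.raises(NumericalError, match="column 0"):
            normalize_features(train, train.copy())


class TestTuning:
    def test_budget_one_returns_single_sample(self):
        x, y = make_gaussian_trials(n_per_class=20, seed=0)
        rng = np.random.default_rng(0)
        spec = tune_hyperparameters(x, y, "svm_rbf", budget=1, rng=rng)
        assert set(spec.params) == {"C", "gamma"}

    def test_separable_data_reaches_perfect_validation(self):
        x, y = make_gaussian_trials(n_per_class=40, d_prime=8.0, seed=1)
        for family in FAMILIES:
            rng = np.random.default_rng(2)
            spec = tune_hyperparameters(x, y, family, budget=15, rng=rng)
            acc = train_and_test(spec, x, y, x, y)
            assert acc >= 0.95

    def test_determinism(self):
        x, y = make_gaussian_trials(n_per_class=20, seed=3)
        s1 = tune_hyperparameters(x, y, "ann", budget=5, rng=np.random.default_rng(9))
        s2 = tune_hyperparameters(x, y, "ann", budget=5, rng=np.random.default_rng(9))
        assert s1.params == s2.params and s1.seed == s2.seed

    def test_invalid_budget_rejected(self):
        x, y = make_gaussian_trials(n_per_class=20)
        with pytest.raises(InvalidParameterError):
            tune_hyperparameters(x, y, "logreg", budget=0)

    def test_unknown_family_rejected(self):
        with pytest.raises(InvalidParameterError):
            sample_config("forest", np.random.default_rng(0))


class TestTrainAndTest:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_separated_gaussians_high_accuracy(self, family):
        """d'=6 classes: every family beats 0.95 (Bayes error ~0.13%)."""
        x_train, y_train = make_gaussian_trials(n_per_class=60, d_prime=6.0, seed=4)
        x_test, y_test = make_gaussian_trials(n_per_class=30, d_prime=6.0, seed=5)
        rng = np.random.default_rng(6)
        spec = tune_hyperparameters(x_train, y_train, family, budget=10, rng=rng)
        acc = train_and_test(spec, x_train, y_train, x_test, y_test)
        assert acc >= 0.95

    def test_shuffled_labels_chance_band(self):
        rng = np.random.default_rng(7)
        x_train, y_train = make_gaussian_trials(n_per_class=60, d_prime=0.0, seed=8)
        x_test, _ = make_gaussian_trials(n_per_class=15, d_prime=0.0, seed=9)
        y_test = rng.integers(0, 2, size=30)
        spec = ClassifierSpec("svm_linear", {"C": 1.0})
        acc = train_and_test(spec, x_train, y_train, x_test, y_test)
        assert 0.35 <= acc <= 0.65

    def test_duplicated_training_set_same_linear_svm_boundary(self):
        x, y = make_gaussian_trials(n_per_class=30, d_prime=3.0, seed=10)
        spec = ClassifierSpec("svm_linear", {"C": 1.0})
        m1 = build_estimator(spec).fit(x, y)
        m2 = build_estimator(spec).fit(np.vstack([x, x]), np.concatenate([y, y]))
        grid = np.random.default_rng(0).standard_normal((50, x.shape[1]))
        np.testing.assert_array_equal(m1.predict(grid), m2.predict(grid))


class TestAnnClassifier:
    def test_learns_separable_data_like_sklearn(self):
        """Our AdamW network matches an sklearn MLP on easy data."""
        from sklearn.neural_network import MLPClassifier

        x, y = make_gaussian_trials(n_per_class=50, d_prime=5.0, seed=11)
        ours = AnnClassifier(
            hidden_units=16, batch_size=16, learning_rate=1e-2,
            weight_decay=1e-4, epochs=100, seed=0,
        ).fit(x, y)
        theirs = MLPClassifier(
            hidden_layer_sizes=(16,), max_iter=500, random_state=0
        ).fit(x, y)
        assert ours.score(x, y) >= 0.95
        assert theirs.score(x, y) >= 0.95

    def test_deterministic_given_seed(self):
        x, y = make_gaussian_trials(n_per_class=20, seed=12)
        a = AnnClassifier(epochs=20, seed=3).fit(x, y).decision_function(x)
        b = AnnClassifier(epochs=20, seed=3).fit(x, y).decision_function(x)
        np.testing.assert_array_equal(a, b)


class TestRunProtocol:
    def test_protocol_arithmetic(self):
        labeled = make_labeled_set(n_trials=320, delta=1.0, seed=13)
        result = run_protocol(
            labeled, families=("svm_linear",), n_repetitions=5, seed=1,
            tuning_budget=2, min_per_class=20,
        )
        a = result.accuracies["svm_linear"]
        assert a.shape == (5, 4)
        assert np.isfinite(a).sum() == 20  # 4 feasible folds x 5 repetitions

    def test_determinism_bit_identical(self):
        labeled = make_labeled_set(n_trials=160, seed=14)
        r1 = run_protocol(labeled, families=("logreg", "ann"), n_repetitions=2,
                          seed=5, tuning_budget=2, min_per_class=10)
        r2 = run_protocol(labeled, families=("logreg", "ann"), n_repetitions=2,
                          seed=5, tuning_budget=2, min_per_class=10)
        for fam in ("logreg", "ann"):
            np.testing.assert_array_equal(r1.accuracies[fam], r2.accuracies[fam])

    def test_signal_recovered_above_chance(self):
        labeled = make_labeled_set(n_trials=320, delta=2.0, seed=15)
        result = run_protocol(labeled, families=("svm_linear",), n_repetitions=2,
                              seed=2, tuning_budget=3, min_per_class=20)
        assert result.per_family_mean["svm_linear"] > 0.8

    def test_infeasible_folds_logged_and_skipped(self):
        labeled = make_labeled_set(n_trials=160, seed=16)
        # make two velocities all-pleasant so other folds' training is starved
        mask = (labeled.velocities == 2.0) | (labeled.velocities == 4.0)
        labeled.labels[mask] = 1
        result = run_protocol(labeled, families=("logreg",), n_repetitions=1,
                              seed=3, tuning_budget=1, min_per_class=30)
        assert len(result.skipped_folds) >= 1
        skipped_v = {s["test_velocity"] for s in result.skipped_folds}
        a = result.accuracies["logreg"][0]
        for i, v in enumerate(result.fold_velocities):
            assert np.isnan(a[i]) == (v in skipped_v)

    def test_unknown_family_rejected(self):
        labeled = make_labeled_set(seed=17)
        with pytest.raises(InvalidParameterError):
            run_protocol(labeled, families=("svm_poly",))
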