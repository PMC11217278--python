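import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from subparc import classify as clf
from subparc import synthio
from subparc.errors import ConfigError, StatsPreconditionError


def brute_force_best_f1(scores, labels):
    best = -1.0
    for thr in np.unique(np.concatenate([scores - 1e-9, scores + 1e-9])):
        pred = scores > thr
        tp = np.sum(pred & labels)
        fp = np.sum(pred & ~labels)
        fn = np.sum(~pred & labels)
        best = max(best, 2 * tp / max(2 * tp + fp + fn, 1))
    return best


def separable_data(n=60, seed=0):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = rng.standard_normal((n, 3))
    X[:, 0] += 6.0 * y
    return X, y


class TestStratifiedSplit:
    def test_paper_sizing_31(self):
        # 67 positives + 86 negatives at 20% -> hold-out of 31 cases
        labels = np.array([1] * 67 + [0] * 86)
        train, test = clf.stratified_split(labels, 0.20, seed=0)
        assert len(test) == 31
        assert len(train) + len(test) == 153
        assert labels[test].sum() == 14  # largest-remainder per class

    def test_paper_sizing_59(self):
        # 208 positives + 86 negatives at 20% -> hold-out of 59 cases
        labels = np.array([1] * 208 + [0] * 86)
        _, test = clf.stratified_split(labels, 0.20, seed=1)
        assert len(test) == 59
        assert labels[test].sum() == 42

    def test_determinism_and_ratio_stability(self):
        labels = np.array([1] * 40 + [0] * 60)
        t1 = clf.stratified_split(labels, 0.2, seed=5)
        t2 = clf.stratified_split(labels, 0.2, seed=5)
        assert np.array_equal(t1[1], t2[1])
        t3 = clf.stratified_split(labels, 0.2, seed=6)
        assert not np.array_equal(t1[1], t3[1])
        assert labels[t1[1]].sum() == labels[t3[1]].sum()

    def test_disjoint_exhaustive(self):
        labels = np.array([1] * 13 + [0] * 17)
        train, test = clf.stratified_split(labels, 0.25, seed=2)
        assert len(np.intersect1d(train, test)) == 0
        assert len(np.union1d(train, test)) == 30

    def test_tiny_class_rejected(self):
        with pytest.raises(StatsPreconditionError):
            clf.stratified_split(np.array([1, 0, 0, 0]), 0.2)


class TestTune:
    def test_single_point_space(self):
        X, y = separable_data()
        spec = clf.ClassifierSpec(
            feature_columns=["a"], positive_class="x", n_trials=5, seed=0,
            space={"n_estimators": ("cat", (50,)),
                   "max_depth": ("cat", (3,)),
                   "min_samples_split": ("cat", (2,)),
                   "max_features": ("cat", ("sqrt",))})
        best, trials = spec and clf.tune(X, y, spec)
        assert best == {"n_estimators": 50, "max_depth": 3,
                        "min_samples_split": 2, "max_features": "sqrt"}
        assert len(trials) == 1  # duplicates skipped

    def test_separable_data_high_auc(self):
        X, y = separable_data()
        spec = clf.ClassifierSpec(feature_columns=["a"], positive_class="x",
                                  n_trials=4, seed=1)
        spec.space = {"n_estimators": ("int", 50, 100),
                      "max_depth": ("cat", (3, None)),
                      "min_samples_split": ("int", 2, 4),
                      "max_features": ("cat", ("sqrt",))}
        _, trials = clf.tune(X, y, spec)
        assert max(trials) >= 0.99

    def test_permuted_labels_no_leakage(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((80, 3))
        y = rng.permutation(np.repeat([0, 1], 40))
        spec = clf.ClassifierSpec(feature_columns=["a"], positive_class="x",
                                  n_trials=3, seed=3)
        spec.space = {"n_estimators": ("cat", (50,)),
                      "max_depth": ("cat", (3,)),
                      "min_samples_split": ("cat", (2,)),
                      "max_features": ("cat", ("sqrt",))}
        _, trials = clf.tune(X, y, spec)
        assert 0.35 <= max(trials) <= 0.65

    def test_single_class_rejected(self):
        X = np.zeros((10, 2))
        spec = clf.ClassifierSpec(feature_columns=["a"], positive_class="x")
        with pytest.raises(StatsPreconditionError):
            clf.tune(X, np.zeros(10), spec)


class TestRocAuc:
    def test_identical_scores_auc_half(self):
        fpr, tpr = clf.roc_curve_points(np.ones(10), np.repeat([0, 1], 5))
        assert clf.auc_trapezoid(fpr, tpr) == pytest.approx(0.5)

    def test_perfect_ordering_auc_one(self):
        scores = np.arange(10.0)
        labels = (scores >= 5).astype(int)
        fpr, tpr = clf.roc_curve_points(scores, labels)
        assert clf.auc_trapezoid(fpr, tpr) == 1.0

    def test_binormal_closed_form(self):
        # oracle: AUC = Phi(d / sqrt(2)) for two unit-variance Gaussians
        # separated by d = 2
        rng = np.random.default_rng(42)
        n = 2000
        scores = np.concatenate([rng.standard_normal(n),
                                 rng.standard_normal(n) + 2.0])
        labels = np.repeat([0, 1], n)
        auc = clf.auc_trapezoid(*clf.roc_curve_points(scores, labels))
        assert auc == pytest.approx(norm.cdf(np.sqrt(2.0)), abs=0.01)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        scores = rng.standard_normal(100)
        labels = rng.integers(0, 2, 100)
        a1 = clf.auc_trapezoid(*clf.roc_curve_points(scores, labels))
        a2 = clf.auc_trapezoid(*clf.roc_curve_points(np.tanh(scores) * 9, labels))
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(11)
        scores = rng.standard_normal(200)
        labels = rng.integers(0, 2, 200)
        ours = clf.auc_trapezoid(*clf.roc_curve_points(scores, labels))
        assert ours == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


class TestF1Threshold:
    def test_worked_example(self):
        thr = clf.f1_threshold(np.array([0.1, 0.4, 0.6, 0.9]),
                               np.array([0, 0, 1, 1]))
        assert thr == pytest.approx(0.5)
        conf = clf.confusion_report(np.array([0.1, 0.4, 0.6, 0.9]),
                                    np.array([0, 0, 1, 1]), thr)
        assert conf["tp"] == 2 and conf["tn"] == 2

    def test_all_positive_threshold_below_min(self):
        scores = np.array([0.3, 0.5, 0.7])
        thr = clf.f1_threshold(scores, np.ones(3, dtype=int))
        assert thr < 0.3

    def test_matches_bruteforce_scan(self, rng):
        for _ in range(100):
            scores = rng.random(20)
            labels = rng.integers(0, 2, 20).astype(bool)
            if not labels.any():
                labels[0] = True
            thr = clf.f1_threshold(scores, labels)
            pred = scores > thr
            tp = np.sum(pred & labels)
            fp = np.sum(pred & ~labels)
            fn = np.sum(~pred & labels)
            f1 = 2 * tp / max(2 * tp + fp + fn, 1)
            assert f1 == pytest.approx(brute_force_best_f1(scores, labels))

    def test_no_positives_rejected(self):
        with pytest.raises(StatsPreconditionError):
            clf.f1_threshold(np.array([0.1, 0.9]), np.array([0, 0]))


class TestConfusionReport:
    def test_balanced_accuracy_is_mean_of_rates(self):
        # sens 1.00 / spec 0.82 -> 0.91
        scores = np.r_[np.ones(14), np.zeros(14), np.ones(3)]
        labels = np.r_[np.ones(14), np.zeros(17)].astype(int)
        conf = clf.confusion_report(scores, labels, 0.5)
        assert conf["sensitivity"] == 1.0
        assert conf["specificity"] == pytest.approx(14 / 17)
        assert conf["balanced_accuracy"] == pytest.approx(
            (conf["sensitivity"] + conf["specificity"]) / 2)
        assert round(conf["balanced_accuracy"], 2) == 0.91

    def test_086_case(self):
        # sens 35/42 = 0.83, spec 15/17 = 0.88 -> balanced accuracy 0.86
        scores = np.r_[np.ones(35), np.zeros(7), np.zeros(15), np.ones(2)]
        labels = np.r_[np.ones(42), np.zeros(17)].astype(int)
        conf = clf.confusion_report(scores, labels, 0.5)
        assert round(conf["sensitivity"], 2) == 0.83
        assert round(conf["specificity"], 2) == 0.88
        assert round(conf["balanced_accuracy"], 2) == 0.86

    def test_symmetric_chance(self):
        scores = np.array([1.0, 0.0, 1.0, 0.0])
        labels = np.array([1, 1, 0, 0])
        conf = clf.confusion_report(scores, labels, 0.5)
        assert conf["balanced_accuracy"] == 0.5


class TestBootstrap:
    def test_constant_features_degenerate_ci(self):
        X = np.zeros((40, 2))
        y = np.repeat([0, 1], 20)
        params = {"n_estimators": 20, "max_depth": 2,
                  "min_samples_split": 2, "max_features": 1.0}
        out = clf.bootstrap_stability(X, y, X[15:25], y[15:25], params,
                                      n_boot=10, seed=0)
        assert np.allclose(out["aucs"], 0.5)
        assert out["ci_high"] - out["ci_low"] == 0.0

    def test_single_resample_degenerate(self):
        X, y = separable_data()
        params = {"n_estimators": 20, "max_depth": 3,
                  "min_samples_split": 2, "max_features": "sqrt"}
        out = clf.bootstrap_stability(X, y, X, y, params, n_boot=1, seed=0)
        assert out["mean"] == out["aucs"][0]
        assert out["ci_low"] == out["ci_high"] == out["mean"]

    def test_separable_high_lower_bound(self):
        X, y = separable_data(n=80, seed=2)
        params = {"n_estimators": 50, "max_depth": 3,
                  "min_samples_split": 2, "max_features": "sqrt"}
        out = clf.bootstrap_stability(X, y, X, y, params, n_boot=30, seed=3)
        assert out["ci_low"] >= 0.9


class TestImportances:
    def test_planted_signal_ranked_first(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 200
            y = np.repeat([0, 1], n // 2)
            X = rng.standard_normal((n, 4))
            X[:, 2] += 2.0 * y
            model = clf._make_rf({"n_estimators": 100, "max_depth": 5,
                                  "min_samples_split": 2,
                                  "max_features": "sqrt"}, seed)
            model.fit(X, y)
            ranking = clf.importance_ranking(model, ["a", "b", "signal", "d"])
            hits += ranking[0][0] == "signal"
        assert hits >= 9

    def test_importances_sum_to_one(self):
        X, y = separable_data()
        model = clf._make_rf({"n_estimators": 30, "max_depth": 3,
                              "min_samples_split": 2,
                              "max_features": "sqrt"}, 0)
        model.fit(X, y)
        ranking = clf.importance_ranking(model, ["a", "b", "c"])
        assert sum(v for _, v in ranking) == pytest.approx(1.0, abs=1e-9)

    def test_exchangeable_noise_no_dominance(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            X = rng.standard_normal((150, 4))
            y = rng.integers(0, 2, 150)
            model = clf._make_rf({"n_estimators": 100, "max_depth": 5,
                                  "min_samples_split": 2,
                                  "max_features": "sqrt"}, seed)
            model.fit(X, y)
            ranking = clf.importance_ranking(model, list("abcd"))
            hits += ranking[0][1] <= 0.5
        assert hits >= 9


class TestNoLeakage:
    def test_poisoned_test_labels_leave_training_untouched(self):
        # audit: flip every test label; the tuned hyperparameters, CV AUCs
        # and fitted importances must not change
        rng = np.random.default_rng(9)
        X = rng.standard_normal((100, 3))
        y = np.repeat([0, 1], 50)
        X[:, 0] += 1.5 * y
        train, test = clf.stratified_split(y, 0.2, seed=0)
        spec = clf.ClassifierSpec(feature_columns=list("abc"),
                                  positive_class="x", n_trials=3, seed=4)
        spec.space = {"n_estimators": ("int", 20, 60),
                      "max_depth": ("cat", (2, 4)),
                      "min_samples_split": ("cat", (2,)),
                      "max_features": ("cat", ("sqrt",))}
        best1, trials1 = clf.tune(X[train], y[train], spec)
        model1, _ = clf.fit_and_test(X[train], y[train], X[test], y[test],
                                     best1, seed=1)
        y_poisoned = y.copy()
        y_poisoned[test] = 1 - y_poisoned[test]
        best2, trials2 = clf.tune(X[train], y_poisoned[train], spec)
        model2, _ = clf.fit_and_test(X[train], y_poisoned[train], X[test],
                                     y_poisoned[test], best2, seed=1)
        assert best1 == best2
        assert trials1 == trials2
        assert np.array_equal(model1.feature_importances_,
                              model2.feature_importances_)


class TestRunClassifier:
    def test_end_to_end_planted_feature(self):
        cohort = synthio.generate_cohort(synthio.CohortSpec(
            n_per_group={"HC": 45, "iRBD": 19, "ePD": 26}, seed=6))
        eff = synthio.EffectSpec(shift=0.06, affected_groups=("iRBD", "ePD"))
        feats = synthio.simulate_features(
            cohort, [eff], columns=["snc_caudal_motor_surface_md"],
            subject_sd=0.03, seed=6)
        spec = clf.ClassifierSpec(
            feature_columns=["snc_caudal_motor_surface_md", "age", "sex", "moca"],
            positive_class="iRBD+ePD", n_trials=4, n_boot=20, seed=6)
        spec.space = {"n_estimators": ("int", 30, 80),
                      "max_depth": ("cat", (3, 5)),
                      "min_samples_split": ("cat", (2,)),
                      "max_features": ("cat", ("sqrt",))}
        report = clf.run_classifier(feats, cohort, spec)
        assert report.test_auc is not None and report.test_auc > 0.7
        assert report.importances[0][0] == "snc_caudal_motor_surface_md"
        assert report.balanced_accuracy == pytest.approx(
            (report.sensitivity + report.specificity) / 2)
        assert report.bootstrap["ci_low"] <= report.bootstrap["mean"] \
            <= report.bootstrap["ci_high"]

    def test_invalid_spec(self):
        with pytest.raises(ConfigError):
            clf.ClassifierSpec(feature_columns=["a"], positive_class="x",
                               test_fraction=1.5)
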