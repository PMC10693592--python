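"""Feature building, grouped CV, metrics, baselines, importances."""

import numpy as np
import pandas as pd
import pytest

from syncom_screen import ml
from syncom_screen.ml import (
    AnalysisConfig,
    FeatureMatrix,
    build_features,
    constant_mean_baseline,
    enumerate_configs,
    evaluate_on_test,
    fit_final,
    grouped_folds,
    grouped_repeated_cv,
    median_importance,
    random_classifier_baseline,
    relative_importance,
)


class TestConfigs:
    def test_twelve_total(self):
        assert len(enumerate_configs()) == 12

    def test_four_classification_eight_regression(self):
        cfgs = enumerate_configs()
        assert sum(c.task == "classification" for c in cfgs) == 4
        assert sum(c.task == "regression" for c in cfgs) == 8

    def test_deterministic_order(self):
        assert [c.label for c in enumerate_configs()] == \
               [c.label for c in enumerate_configs()]

    def test_classification_presence_only(self):
        with pytest.raises(ValueError):
            AnalysisConfig("RF", "classification", "colonization", "median")


class TestFeatures:
    def test_presence_rows_have_exactly_k_ones(self, canonical_screen):
        train, _, _ = canonical_screen
        fm = build_features(train, "presence", "median", "regression")
        assert (fm.X.sum(axis=1) == 5).all()
        assert fm.X.shape == (136, 35)

    def test_individual_level_row_count(self, canonical_screen):
        train, _, _ = canonical_screen
        fm = build_features(train, "presence", "individual", "regression")
        assert len(fm.X) == 544  # 136 communities x 4 plants

    def test_colonization_respects_membership(self, canonical_screen):
        train, _, _ = canonical_screen
        fm = build_features(train, "colonization", "median", "regression")
        members = train.communities.membership()
        for cid in fm.X.index[:10]:
            absent = [s for s in fm.X.columns if s not in members[cid]]
            assert (fm.X.loc[cid, absent] == 0).all()


class TestGroupedCV:
    def _fm(self, n_groups=20, rows_per=4, seed=0):
        rng = np.random.default_rng(seed)
        groups = np.repeat([f"C{i}" for i in range(n_groups)], rows_per)
        X = pd.DataFrame(rng.normal(size=(len(groups), 5)))
        y = pd.Series(rng.normal(size=len(groups)))
        return FeatureMatrix(X, y, pd.Series(groups), pd.Series(["e1"] * len(groups)),
                             "individual", "presence")

    def test_no_group_straddles_folds(self):
        fm = self._fm()
        folds = grouped_folds(fm.groups, n_folds=5, n_repeats=10, seed=3)
        assert len(folds) == 10
        g = fm.groups.to_numpy()
        for repeat in folds:
            assert len(repeat) == 5
            seen = {}
            for fi, rows in enumerate(repeat):
                for grp in np.unique(g[rows]):
                    assert grp not in seen, "group leaked across folds"
                    seen[grp] = fi
            assert len(seen) == 20  # partition is exhaustive

    def test_fifty_fold_evaluations(self):
        fm = self._fm()
        folds = grouped_folds(fm.groups, 5, 10, seed=1)
        assert sum(len(r) for r in folds) == 50

    def test_single_candidate_identity(self):
        fm = self._fm()
        cfg = AnalysisConfig("RF", "regression", "presence", "individual")
        out = grouped_repeated_cv(fm, cfg, seed=0, grid=[{"max_features": 2}])
        assert out == {"max_features": 2}

    def test_too_few_groups_rejected(self):
        fm = self._fm(n_groups=3)
        with pytest.raises(ValueError):
            grouped_folds(fm.groups, n_folds=5, n_repeats=1, seed=0)


class TestEvaluation:
    def _report(self, tp, fn, fp, tn):
        y_true = ["protected"] * (tp + fn) + ["non_protected"] * (fp + tn)
        y_pred = (["protected"] * tp + ["non_protected"] * fn
                  + ["protected"] * fp + ["non_protected"] * tn)
        return ml._confusion_metrics(np.array(y_true), np.array(y_pred))

    def test_perfect_predictions(self):
        m = self._report(10, 0, 0, 20)
        assert m["precision"] == m["recall"] == m["specificity"] == 1.0

    def test_published_definition_arithmetic(self):
        m = self._report(tp=14, fn=1, fp=4, tn=51)
        assert m["recall"] == pytest.approx(14 / 15)
        assert m["precision"] == pytest.approx(14 / 18)
        assert m["specificity"] == pytest.approx(51 / 55)

    def test_random_fixture_matches_confusion_oracle(self):
        rng = np.random.default_rng(0)
        y_true = np.where(rng.random(200) < 0.3, "protected", "non_protected")
        y_pred = np.where(rng.random(200) < 0.5, "protected", "non_protected")
        m = ml._confusion_metrics(y_true, y_pred)
        tp = np.sum((y_true == "protected") & (y_pred == "protected"))
        fn = np.sum((y_true == "protected") & (y_pred == "non_protected"))
        assert m["recall"] == pytest.approx(tp / (tp + fn))

    def test_regression_rmse(self):
        cfg = AnalysisConfig("RF", "regression", "presence", "median")

        class _Const:
            def predict(self, X):
                return np.zeros(len(X))

        fm = FeatureMatrix(pd.DataFrame(np.zeros((2, 3))),
                           pd.Series([-2.0, 2.0]), pd.Series(["a", "b"]),
                           pd.Series(["e1", "e1"]), "median", "presence")
        rep = evaluate_on_test(_Const(), fm, cfg)
        assert rep.metrics["rmse"] == pytest.approx(2.0)


class TestBaselines:
    def test_random_classifier_analytics(self):
        rng = np.random.default_rng(1)
        train = pd.Series(np.where(rng.random(500) < 0.4, "protected", "non_protected"))
        test = pd.Series(np.where(rng.random(400) < 0.25, "protected", "non_protected"))
        rep = random_classifier_baseline(train, test, reps=4000, seed=2)
        prev_train = (train == "protected").mean()
        prev_test = (test == "protected").mean()
        # E[recall] = assignment probability; E[precision] = test prevalence
        se = 3 / np.sqrt(4000)
        assert rep.metrics["recall"] == pytest.approx(prev_train, abs=5 * se)
        assert rep.metrics["precision"] == pytest.approx(prev_test, abs=0.02)

    def test_constant_mean_closed_form(self):
        train = np.array([1.0, 3.0])   # mean 2
        test = np.array([0.0, 4.0])
        assert constant_mean_baseline(train, test) == pytest.approx(2.0)
        assert constant_mean_baseline(train, np.array([2.0, 2.0])) == 0.0
        rng = np.random.default_rng(3)
        resp = rng.normal(1.0, 2.0, 5000)
        rmse = constant_mean_baseline(np.array([0.0]), resp)
        assert rmse == pytest.approx(np.sqrt(4.0 + 1.0), rel=0.05)  # sqrt(var+bias^2)


class TestImportance:
    def _single_effect_fm(self, n=200, seed=4):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.integers(0, 2, size=(n, 10)).astype(float),
                         columns=[f"S{i:02d}" for i in range(10)])
        y = pd.Series(np.where(X["S03"] == 1, "protected", "non_protected"))
        groups = pd.Series([f"C{i}" for i in range(n)])
        return FeatureMatrix(X, y, groups, pd.Series(["e1"] * n), "median", "presence")

    def test_informative_feature_ranks_first_with_100(self):
        fm = self._single_effect_fm()
        cfg = AnalysisConfig("RF", "classification", "presence", "median")
        model = fit_final(fm, cfg, {"max_features": 3}, seed=0)
        imp = relative_importance(model, fm, cfg, seed=0)
        assert imp.idxmax() == "S03"
        assert imp.max() == pytest.approx(100.0)

    def test_glmnet_importance_from_coefficients(self):
        fm = self._single_effect_fm()
        cfg = AnalysisConfig("GLMNet", "classification", "presence", "median")
        model = fit_final(fm, cfg, {"alpha": 0.01, "l1_ratio": 0.5}, seed=0)
        imp = relative_importance(model, fm, cfg)
        assert imp.idxmax() == "S03"

    def test_median_aggregation_matches_sort_oracle(self):
        tables = [pd.Series({"A": 10.0, "B": 50.0}),
                  pd.Series({"A": 30.0, "B": 40.0}),
                  pd.Series({"A": 20.0, "B": 90.0})]
        med = median_importance(tables)
        assert med["A"] == 20.0 and med["B"] == 50.0
        assert list(med.index) == ["B", "A"]


class TestThresholdSensitivity:
    def test_refit_rank_stability_on_canonical_screen(self, canonical_screen):
        train, _, _ = canonical_screen
        fm = build_features(train, "presence", "median", "classification")
        raw = build_features(train, "presence", "median", "regression").y
        cfg = AnalysisConfig("RF", "classification", "presence", "median")
        base_thr = ml.classification_thresholds(train)
        thresholds = [{e: t + d for e, t in base_thr.items()} for d in (-0.2, 0.0, 0.2)]
        report = ml.threshold_sensitivity_refit(
            fm, fm.experiment, thresholds, raw, cfg, {"max_features": 8}, seed=0)
        assert len(report) == 3
        # implanted strong strains stay highly ranked across refits
        top = report[["S01", "S02", "S03"]]
        assert (top <= 6).all().all()

    def test_identical_thresholds_identical_ranks(self, canonical_screen):
        train, _, _ = canonical_screen
        fm = build_features(train, "presence", "median", "classification")
        raw = build_features(train, "presence", "median", "regression").y
        cfg = AnalysisConfig("RF", "classification", "presence", "median")
        thr = ml.classification_thresholds(train)
        rep = ml.threshold_sensitivity_refit(fm, fm.experiment, [thr, thr], raw,
                                             cfg, {"max_features": 8}, seed=1)
        assert (rep.iloc[0] == rep.iloc[1]).all()
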