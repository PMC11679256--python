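"""Feature voting, splitting, grid search, evaluation and the ensemble."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pdstages.classify import (
    ImportanceVoteSelector,
    StagedEnsembleClassifier,
    default_grids,
    ensemble_predict,
    evaluate,
    grid_search_fit,
    metrics_from_confusion,
    rf_feature_vote,
    run_experiment,
    split_train_test,
)
from pdstages.synthetic import CohortConfig, FeatureEffect, generate_feature_cohort, null_config


def _two_group_table(n=40, n_features=8, effect_col=0, d=0.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n, n_features))
    y = np.array(["A"] * n + ["B"] * n)
    X[n:, effect_col] += d
    cols = [f"f{j}" for j in range(n_features)]
    table = pd.DataFrame(X, columns=cols)
    table["group"] = y
    return table


class TestFeatureVoting:
    def test_strong_column_ranks_first(self):
        """A single d=2 column out of many nulls tops the importance
        ranking in at least 95% of seeded replicates."""
        hits = 0
        n_rep = 100
        for seed in range(n_rep):
            table = _two_group_table(n=56, n_features=20, effect_col=3, d=2.0, seed=seed)
            ranking, _ = rf_feature_vote(table.drop(columns="group"), table["group"], seed=seed)
            hits += ranking["feature"].iloc[0] == "f3"
        assert hits / n_rep >= 0.95

    def test_topk_with_large_k_keeps_all(self):
        table = _two_group_table(n=20, n_features=5)
        ranking, selected = rf_feature_vote(table.drop(columns="group"), table["group"], policy=50, seed=0)
        assert len(selected) == 5
        assert selected == list(ranking["feature"])  # importance order

    def test_single_class_rejected(self):
        table = _two_group_table(n=10)
        with pytest.raises(ValueError, match="two classes"):
            ImportanceVoteSelector().fit(table.drop(columns="group"), ["A"] * 20)

    def test_selector_transform_shape(self):
        table = _two_group_table(n=30, n_features=10, effect_col=1, d=2.0, seed=1)
        sel = ImportanceVoteSelector(policy=3, random_state=1).fit(
            table.drop(columns="group"), table["group"]
        )
        assert sel.transform(table.drop(columns="group")).shape == (60, 3)


class TestSplit:
    def test_balanced_112_rows_give_17_per_class(self):
        table = _two_group_table(n=56)
        train, test = split_train_test(table, test_fraction=0.3, seed=0)
        assert len(test) == 34
        assert (test["group"].value_counts() == 17).all()
        assert len(train) + len(test) == 112
        assert set(train.index).isdisjoint(test.index)

    def test_degenerate_fraction_rejected(self):
        table = _two_group_table(n=10)
        with pytest.raises(ValueError):
            split_train_test(table, test_fraction=0.0)

    def test_seed_determinism(self):
        table = _two_group_table(n=30)
        a1, _ = split_train_test(table, seed=5)
        a2, _ = split_train_test(table, seed=5)
        b1, _ = split_train_test(table, seed=6)
        assert list(a1.index) == list(a2.index)
        assert list(a1.index) != list(b1.index)


class TestGridSearch:
    def test_single_point_grid_returned(self):
        table = _two_group_table(n=20, d=3.0)
        model, params = grid_search_fit(
            "LR", table.drop(columns="group"), table["group"], grid={"C": [0.5]}, seed=0
        )
        assert params == {"C": 0.5}

    def test_separable_data_all_families_perfect(self):
        from sklearn.model_selection import StratifiedKFold, cross_val_score

        table = _two_group_table(n=30, n_features=3, effect_col=0, d=20.0, seed=2)
        X, y = np.asarray(table.drop(columns="group"), float), table["group"]
        for family in ("LR", "RF", "SVC"):
            model, _ = grid_search_fit(family, X, y, seed=0)
            cv = StratifiedKFold(5, shuffle=True, random_state=0)
            assert cross_val_score(model, X, y, cv=cv).mean() == 1.0

    def test_default_grids_cover_reference_settings(self):
        g = default_grids()
        assert 75 in g["RF"]["n_estimators"] and 3 in g["RF"]["max_depth"]
        assert 4 in g["RF"]["min_samples_leaf"] and 2 in g["RF"]["min_samples_split"]
        assert 10.0 in g["SVC"]["C"] and 0.01 in g["SVC"]["gamma"]
        assert {0.1, 1.0} <= set(g["LR"]["C"]) and 100 in g["LR"]["max_iter"]

    def test_small_class_reduces_folds_with_warning(self):
        table = _two_group_table(n=3, d=5.0)
        with pytest.warns(UserWarning, match="reducing CV folds"):
            grid_search_fit("LR", table.drop(columns="group"), table["group"], grid={"C": [1.0]}, cv_folds=5)


class TestEvaluate:
    def test_printed_confusion_metrics(self):
        """17-per-class test set with 3+2 misclassifications: accuracy
        29/34 = 0.85, weighted precision about 0.854."""
        m = metrics_from_confusion([[14, 3], [2, 15]])
        assert round(m["accuracy"], 2) == 0.85
        assert m["precision"] == pytest.approx(0.8542, abs=1e-3)
        assert m["recall"] == pytest.approx(29 / 34)

    def test_metrics_match_independent_formula_oracle(self, rng):
        for _ in range(20):
            cm = rng.integers(0, 30, size=(2, 2)).astype(float)
            if cm.sum() == 0 or (cm.sum(axis=1) == 0).any():
                continue
            m = metrics_from_confusion(cm)
            tn, fp, fn, tp = cm.ravel()
            acc = (tn + tp) / cm.sum()
            assert m["accuracy"] == pytest.approx(acc, abs=1e-12)
            prec0 = tn / (tn + fn) if tn + fn else 0.0
            prec1 = tp / (tp + fp) if tp + fp else 0.0
            w0, w1 = (tn + fp) / cm.sum(), (fn + tp) / cm.sum()
            assert m["precision"] == pytest.approx(w0 * prec0 + w1 * prec1, abs=1e-12)

    def test_perfect_model(self):
        table = _two_group_table(n=30, d=8.0, seed=3)
        model, _ = grid_search_fit("LR", table.drop(columns="group"), table["group"], seed=0)
        rep = evaluate(model, table.drop(columns="group"), table["group"], family="LR", positive="B")
        assert rep.accuracy == 1.0
        assert rep.auc == pytest.approx(1.0)
        assert np.trace(rep.confusion) == len(table)

    def test_auc_invariant_under_monotone_score_transform(self, rng):
        from sklearn.metrics import auc as sk_auc
        from sklearn.metrics import roc_curve

        y = rng.integers(0, 2, size=200)
        s = rng.normal(size=200) + y
        fpr1, tpr1, _ = roc_curve(y, s)
        fpr2, tpr2, _ = roc_curve(y, np.exp(3 * s))  # strictly increasing transform
        assert sk_auc(fpr1, tpr1) == pytest.approx(sk_auc(fpr2, tpr2), abs=1e-12)

    def test_random_scores_near_chance(self, rng):
        from sklearn.metrics import auc as sk_auc
        from sklearn.metrics import roc_curve

        y = np.repeat([0, 1], 500)
        fpr, tpr, _ = roc_curve(y, rng.normal(size=1000))
        assert sk_auc(fpr, tpr) == pytest.approx(0.5, abs=0.06)


class _StubBinary:
    def __init__(self, classes, probs):
        self.classes_ = np.array(classes)
        self._p = np.asarray(probs, dtype=float)

    def predict_proba(self, X):
        return np.tile(self._p, (len(X), 1))


class TestEnsemble:
    def _features(self):
        return pd.DataFrame({"f1": [0.0]})

    def test_unanimous_certainty_is_high_tier(self):
        """Both PD-aware models certain of PD (the HC-vs-PR model, which
        never sees PD, stays agnostic) -> PD with a high-confidence tier."""
        models = {
            ("CONTROL", "PARKINSON"): (_StubBinary(["CONTROL", "PARKINSON"], [0.0, 1.0]), ["f1"]),
            ("CONTROL", "PRODROMAL"): (_StubBinary(["CONTROL", "PRODROMAL"], [0.5, 0.5]), ["f1"]),
            ("PARKINSON", "PRODROMAL"): (_StubBinary(["PARKINSON", "PRODROMAL"], [1.0, 0.0]), ["f1"]),
        }
        (out,) = ensemble_predict(models, self._features())
        assert out.predicted == "PARKINSON"
        assert out.probabilities["PARKINSON"] == pytest.approx(2 / 3)
        assert out.tier == "high"

    def test_uniform_probabilities_tie_breaks_to_first_class(self):
        models = {
            ("CONTROL", "PARKINSON"): (_StubBinary(["CONTROL", "PARKINSON"], [0.5, 0.5]), ["f1"]),
            ("CONTROL", "PRODROMAL"): (_StubBinary(["CONTROL", "PRODROMAL"], [0.5, 0.5]), ["f1"]),
            ("PARKINSON", "PRODROMAL"): (_StubBinary(["PARKINSON", "PRODROMAL"], [0.5, 0.5]), ["f1"]),
        }
        (out,) = ensemble_predict(models, self._features())
        assert out.predicted == "CONTROL"  # fixed class order
        assert out.tier == "extremely low"

    def test_score_conservation(self):
        """Normalised scores are raw sums divided by the number of
        contributing models: they sum to one and keep proportions."""
        models = {
            ("CONTROL", "PARKINSON"): (_StubBinary(["CONTROL", "PARKINSON"], [0.7, 0.3]), ["f1"]),
            ("CONTROL", "PRODROMAL"): (_StubBinary(["CONTROL", "PRODROMAL"], [0.6, 0.4]), ["f1"]),
            ("PARKINSON", "PRODROMAL"): (_StubBinary(["PARKINSON", "PRODROMAL"], [0.2, 0.8]), ["f1"]),
        }
        (out,) = ensemble_predict(models, self._features())
        assert sum(out.probabilities.values()) == pytest.approx(1.0)
        assert out.probabilities["CONTROL"] == pytest.approx(1.3 / 3)

    def test_missing_feature_columns_rejected(self):
        models = {("CONTROL", "PARKINSON"): (_StubBinary(["CONTROL", "PARKINSON"], [1, 0]), ["nope"])}
        with pytest.raises(ValueError, match="missing columns"):
            ensemble_predict(models, self._features())


class TestExperiments:
    def test_three_tasks_three_families(self, experiments):
        assert len(experiments) == 3
        for task, res in experiments.items():
            assert set(res.reports) == {"LR", "RF", "SVC"}
            assert len(res.selected_features) >= 1
            for rep in res.reports.values():
                assert 0.0 <= rep.accuracy <= 1.0
                assert rep.confusion.sum() == 34  # 30% of 112

    def test_effect_cohort_beats_chance(self, experiments):
        for task, res in experiments.items():
            assert res.reports[res.best_family].accuracy > 0.64  # binomial 95% bound, n=34

    def test_staged_classifier_fit_predict(self, fast_cohort):
        table, _ = fast_cohort
        X, y = table.drop(columns="group"), table["group"]
        clf = StagedEnsembleClassifier(random_state=0).fit(X, y)
        pred = clf.predict(X)
        assert set(pred) <= set(y)
        assert (pred == y).mean() > 1 / 3
        proba = clf.predict_proba(X.iloc[:5])
        assert proba.shape == (5, 3)
        assert proba.sum(axis=1) == pytest.approx(np.ones(5))

    def test_sklearn_params_roundtrip(self):
        from sklearn.base import clone

        clf = StagedEnsembleClassifier(policy=5, random_state=3)
        assert clone(clf).get_params()["policy"] == 5

    def test_missing_group_rejected(self, fast_cohort):
        table, _ = fast_cohort
        sub = table[table["group"] != "PRODROMAL"]
        from pdstages.classify import run_three_experiments

        with pytest.raises(ValueError, match="lacks groups"):
            run_three_experiments(sub, seed=0)
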