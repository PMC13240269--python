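"""Subject-wise cross-validation, metrics, bootstrap and summary tests."""

import numpy as np
import pandas as pd
import pytest

from netstab import (
    CVConfig,
    DataError,
    ParameterError,
    SubjectPrediction,
    aggregate_subject,
    bootstrap_ci,
    compute_metrics,
    fit_with_inner_cv,
    group_summary_test,
    nested_cv,
    outer_folds,
)


class TestOuterFolds:
    def test_partition_into_disjoint_test_sets(self):
        ids = [f"s{i}" for i in range(10)]
        labels = ["P"] * 5 + ["HC"] * 5
        folds = outer_folds(ids, labels, 5, seed=0)
        seen = []
        for train, test in folds:
            assert len(test) == 2
            assert not set(train) & set(test)
            seen += test
        assert sorted(seen) == sorted(ids)

    def test_study_sized_cohort_stratification(self):
        """19 patients + 24 controls over 5 folds: >= 3 of each class per fold."""
        ids = [f"P{i}" for i in range(19)] + [f"H{i}" for i in range(24)]
        labels = ["P"] * 19 + ["HC"] * 24
        for train, test in outer_folds(ids, labels, 5, seed=3):
            test_labels = ["P" if t.startswith("P") else "HC" for t in test]
            assert test_labels.count("P") >= 3
            assert test_labels.count("HC") >= 3

    def test_too_many_folds_rejected(self):
        with pytest.raises(ParameterError):
            outer_folds(["a", "b", "c"], ["P", "P", "HC"], 4, seed=0)
        with pytest.raises(ParameterError):
            outer_folds(["a", "b", "c", "d"], ["P", "P", "P", "HC"], 2, seed=0)


class TestAggregateSubject:
    def test_arithmetic_mean(self):
        assert aggregate_subject([0.2, 0.4, 0.6]) == pytest.approx(0.4)
        assert aggregate_subject([0.9, 0.9, 0.9]) == pytest.approx(0.9)

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            aggregate_subject([])

    def test_aggregation_shrinks_variance(self, rng):
        """The subject mean of n epoch probabilities has variance ~ var/n."""
        n, reps = 25, 4000
        draws = rng.uniform(0.2, 0.8, size=(reps, n))
        agg_var = draws.mean(axis=1).var()
        epoch_var = draws.var()
        assert agg_var == pytest.approx(epoch_var / n, rel=0.1)


def _preds(probs, labels):
    return [
        SubjectPrediction(f"s{i}", lab, p, fold=0)
        for i, (p, lab) in enumerate(zip(probs, labels))
    ]


class TestComputeMetrics:
    def test_perfect_separation(self):
        preds = _preds([0.9, 0.8, 0.2, 0.1], ["P", "P", "HC", "HC"])
        m = compute_metrics(preds)
        assert m == {"accuracy": 1.0, "recall": 1.0, "specificity": 1.0, "auc": 1.0}

    def test_hand_enumerated_confusion_table(self):
        # TP=3, FN=1, TN=4, FP=0
        probs = [0.9, 0.8, 0.7, 0.2, 0.4, 0.3, 0.2, 0.1]
        labels = ["P"] * 4 + ["HC"] * 4
        m = compute_metrics(_preds(probs, labels))
        assert m["recall"] == pytest.approx(0.75)
        assert m["specificity"] == pytest.approx(1.0)
        assert m["accuracy"] == pytest.approx(0.875)

    def test_complete_ties_give_chance_auc(self):
        preds = _preds([0.5] * 6, ["P", "P", "P", "HC", "HC", "HC"])
        assert compute_metrics(preds)["auc"] == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            compute_metrics(_preds([0.9, 0.8], ["P", "P"]))


class TestBootstrapCI:
    def test_degenerate_perfect_predictions(self):
        preds = _preds([0.9, 0.9, 0.1, 0.1], ["P", "P", "HC", "HC"])
        lo, hi = bootstrap_ci(preds, "accuracy", n_boot=500, seed=0)
        assert (lo, hi) == (1.0, 1.0)

    def test_brackets_point_estimate(self, rng):
        probs = np.clip(rng.normal([0.7] * 10 + [0.3] * 10, 0.25), 0, 1)
        preds = _preds(probs, ["P"] * 10 + ["HC"] * 10)
        point = compute_metrics(preds)["auc"]
        lo, hi = bootstrap_ci(preds, "auc", n_boot=2000, seed=1)
        assert lo <= point <= hi

    def test_deterministic_given_seed(self, rng):
        probs = np.clip(rng.normal([0.7] * 8 + [0.3] * 8, 0.3), 0, 1)
        preds = _preds(probs, ["P"] * 8 + ["HC"] * 8)
        assert bootstrap_ci(preds, "accuracy", 1000, seed=5) == bootstrap_ci(
            preds, "accuracy", 1000, seed=5
        )

    def test_small_b_warns(self):
        preds = _preds([0.9, 0.1, 0.8, 0.2], ["P", "HC", "P", "HC"])
        with pytest.warns(UserWarning, match="small"):
            bootstrap_ci(preds, "accuracy", n_boot=50, seed=0)

    def test_coverage_near_nominal(self, rng):
        """CI coverage across simulated datasets at true accuracy 0.8."""
        n, true_acc, hits, sims = 40, 0.8, 0, 200
        for s in range(sims):
            r = np.random.default_rng(s)
            labels = ["P"] * (n // 2) + ["HC"] * (n // 2)
            correct = r.random(n) < true_acc
            probs = np.where(
                correct, [0.9] * (n // 2) + [0.1] * (n // 2),
                [0.1] * (n // 2) + [0.9] * (n // 2),
            )
            preds = _preds(probs, labels)
            lo, hi = bootstrap_ci(preds, "accuracy", n_boot=2000, seed=s)
            hits += lo <= true_acc <= hi
        assert 0.88 <= hits / sims <= 0.99


class TestGroupSummaryTest:
    def test_published_epoch_count_comparison(self):
        """492.8+-38.7 (n=19) vs 513.8+-25.5 (n=24): d ~ 0.66, Welch t ~ -2.04.

        The t recomputed from rounded summaries differs in the last digit
        from the raw-data value (-2.05); equality is deliberately not forced.
        """
        res = group_summary_test(492.8, 38.7, 19, 513.8, 25.5, 24)
        assert abs(res["cohen_d"]) == pytest.approx(0.66, abs=0.005)
        assert res["welch_t"] == pytest.approx(-2.04, abs=0.005)
        assert res["welch_t"] != pytest.approx(-2.05, abs=0.001)

    def test_equal_means_give_zero(self):
        res = group_summary_test(10.0, 2.0, 10, 10.0, 3.0, 12)
        assert res["welch_t"] == 0.0
        assert res["cohen_d"] == 0.0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ParameterError):
            group_summary_test(1.0, 1.0, 1, 2.0, 1.0, 10)
        with pytest.raises(ParameterError):
            group_summary_test(1.0, 0.0, 5, 2.0, 0.0, 10)


class TestFitWithInnerCV:
    def test_separable_table_reaches_perfect_training_accuracy(self, toy_table):
        cfg = CVConfig(seed=0, inner_folds=2, n_select=2)
        fit = fit_with_inner_cv(toy_table, cfg)
        pred = fit.model.predict(
            toy_table.features[fit.selected_features].to_numpy()
        )
        assert (pred == toy_table.labels.to_numpy()).mean() == 1.0
        assert "signal" in fit.selected_features

    def test_deterministic_hyperparameters(self, toy_table):
        cfg = CVConfig(seed=3, inner_folds=2, n_select=2)
        a = fit_with_inner_cv(toy_table, cfg)
        b = fit_with_inner_cv(toy_table, cfg)
        assert a.best_params == b.best_params
        assert a.selected_features == b.selected_features

    def test_single_class_rejected(self, toy_table):
        from netstab.network import FeatureTable

        mask = toy_table.labels == "P"
        broken = FeatureTable(
            toy_table.features[mask.to_numpy()].reset_index(drop=True),
            toy_table.labels[mask.to_numpy()].reset_index(drop=True),
            toy_table.subjects[mask.to_numpy()].reset_index(drop=True),
        )
        with pytest.raises(DataError):
            fit_with_inner_cv(broken, CVConfig(seed=0))

    def test_label_permutation_scores_near_chance(self, toy_table):
        """Inner-CV accuracy on permuted labels hovers around 0.5."""
        from netstab.network import FeatureTable

        scores = []
        for s in range(10):
            r = np.random.default_rng(s)
            perm = toy_table.labels.to_numpy()[r.permutation(toy_table.n_rows)]
            table = FeatureTable(
                toy_table.features, pd.Series(perm, name="label"),
                toy_table.subjects,
            )
            try:
                fit = fit_with_inner_cv(table, CVConfig(seed=s, inner_folds=2,
                                                        n_select=2))
            except DataError:
                continue
            pred = fit.model.predict(
                table.features[fit.selected_features].to_numpy()
            )
            # out-of-sample behaviour is what matters; training accuracy on
            # permuted labels may overfit, so judge via fresh noise rows
            fresh = pd.DataFrame(
                np.random.default_rng(100 + s).normal(
                    size=(40, len(fit.selected_features))
                ),
                columns=fit.selected_features,
            )
            p = fit.model.predict_proba(fresh.to_numpy())[:, 1]
            scores.append(p.mean())
        assert 0.2 < np.mean(scores) < 0.8


class TestNestedCV:
    def test_out_of_fold_coverage_and_determinism(self, toy_table):
        cfg = CVConfig(seed=1, outer_folds=5, inner_folds=2, n_select=2,
                       bootstrap_iterations=500, compute_shap=False)
        res = nested_cv(toy_table, cfg)
        assert len(res.predictions) == toy_table.n_rows
        assert len({p.subject_id for p in res.predictions}) == toy_table.n_rows
        res2 = nested_cv(toy_table, cfg)
        probs1 = {p.subject_id: p.probability for p in res.predictions}
        probs2 = {p.subject_id: p.probability for p in res2.predictions}
        assert probs1 == probs2

    def test_separable_table_classified_perfectly(self, toy_table):
        cfg = CVConfig(seed=2, outer_folds=5, inner_folds=2, n_select=2,
                       bootstrap_iterations=500, compute_shap=True)
        res = nested_cv(toy_table, cfg)
        assert res.metrics.pooled["auc"] == pytest.approx(1.0)
        lo, hi = res.metrics.ci["accuracy"]
        assert lo <= res.metrics.pooled["accuracy"] <= hi
        assert res.shap_summary is not None
        # the informative column dominates the Shapley summary
        top = (
            res.shap_summary.groupby("feature")["mean_abs_shap"].mean().idxmax()
        )
        assert top == "signal"
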