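"""Feature selection, per-exercise models, aggregation and scoring."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neuroscreen import (
    ExerciseEnsembleClassifier,
    TTestCorrelationSelector,
    aggregate_outputs,
    augment_dataset,
    evaluate,
    select_features,
    simulate_feature_cohort,
    split_dataset,
    train_exercise_model,
)
from neuroscreen.classification import grid_search_model
from neuroscreen.cohort import CohortDataset
from neuroscreen.synthetic_data import CohortSimSpec


def pooled_t_power(mean_diff, sd1, sd2, n_per_class, alpha=0.05):
    """Analytic power of the pooled two-sample t-test (the selection oracle)."""
    sp = np.sqrt((sd1**2 + sd2**2) / 2)
    nc = mean_diff / (sp * np.sqrt(2 / n_per_class))
    df = 2 * n_per_class - 2
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc)


class TestFeatureSelection:
    def test_duplicate_columns_keep_exactly_one(self, rng):
        x = rng.normal(size=200)
        y = (np.arange(200) < 100).astype(int)
        x = x + y  # informative
        X = pd.DataFrame({"a": x, "b": x})
        sel = TTestCorrelationSelector().fit(X, y)
        assert len(sel.selected_features_) == 1

    def test_noise_eliminated_effect_retained(self):
        """d=2 effect vs pure-noise feature at n=400: noise survives only
        at the false-positive rate."""
        kept_effect = kept_noise = 0
        runs = 100
        for seed in range(runs):
            r = np.random.default_rng(seed)
            y = np.repeat([0, 1], 200)
            X = pd.DataFrame(
                {"effect": r.normal(size=400) + 2.0 * y, "noise": r.normal(size=400)}
            )
            sel = TTestCorrelationSelector().fit(X, y)
            kept_effect += "effect" in sel.selected_features_
            kept_noise += "noise" in sel.selected_features_
        assert kept_effect >= 95
        assert kept_noise <= runs * 0.05 + 3 * np.sqrt(runs * 0.05 * 0.95)

    def test_published_heel_toe_effect_sizes(self):
        """Published group summaries for the walk features at n=200/class:
        the strong feature is always kept; the weak feature's retention
        frequency matches the analytic t-test power."""
        runs, n = 100, 200
        kept = {"feature_1": 0, "feature_2": 0}
        for seed in range(runs):
            r = np.random.default_rng(1000 + seed)
            y = np.repeat([0, 1], n)  # 1 = neuropathy
            X = pd.DataFrame(
                {
                    "feature_1": np.where(
                        y, r.normal(0.005, 0.003, 2 * n), r.normal(0.011, 0.005, 2 * n)
                    ),
                    "feature_2": np.where(
                        y, r.normal(1.402, 0.334, 2 * n), r.normal(1.481, 0.369, 2 * n)
                    ),
                }
            )
            sel = TTestCorrelationSelector().fit(X, y)
            for name in kept:
                kept[name] += name in sel.selected_features_
        assert kept["feature_1"] >= 95
        power2 = pooled_t_power(1.481 - 1.402, 0.369, 0.334, n)
        se = np.sqrt(runs * power2 * (1 - power2))
        assert abs(kept["feature_2"] - runs * power2) < 3 * se

    def test_no_survivor_raises(self, rng):
        y = np.repeat([0, 1], 50)
        X = pd.DataFrame({"noise": rng.normal(size=100)})
        with pytest.raises(ValueError, match="relax"):
            TTestCorrelationSelector(p_threshold=1e-6).fit(X, y)

    def test_wrapper_selects_for_one_exercise(self, pilot_cohort):
        names = select_features(pilot_cohort, "heel_toe_walk", p_threshold=0.5)
        assert names and all(n.startswith("heel_toe_walk__") for n in names)


class TestTrainExerciseModel:
    @pytest.mark.parametrize("kind", ["svm", "logistic_regression", "decision_tree"])
    def test_separable_blobs_perfect_training_accuracy(self, kind, rng):
        X = np.vstack([rng.normal(0, 0.3, (50, 2)), rng.normal(5, 0.3, (50, 2))])
        y = np.repeat([0, 1], 50)
        search = grid_search_model(X, y, kind, seed=0)
        assert search.best_estimator_.score(X, y) == 1.0

    def test_permuted_labels_near_chance(self, rng):
        X = rng.normal(size=(400, 3))
        y = rng.permutation(np.repeat([0, 1], 200))
        search = grid_search_model(X, y, "logistic_regression", seed=0)
        assert 0.4 <= search.best_score_ <= 0.6

    def test_same_seed_same_hyperparameters(self, pilot_cohort):
        aug = augment_dataset(pilot_cohort, 50, 50, seed=4)
        runs = [
            train_exercise_model(aug, "romberg", "decision_tree", seed=11).best_params_
            for _ in range(2)
        ]
        assert runs[0] == runs[1]

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(20, 2))
        with pytest.raises(ValueError, match="single class"):
            grid_search_model(X, np.zeros(20, dtype=int), "svm", seed=0)


class TestSplitDataset:
    def test_423_rows_split_296_127(self, pilot_cohort):
        aug = augment_dataset(pilot_cohort, seed=0)
        train, test = split_dataset(aug, 0.7, seed=0)
        assert abs(len(train) - 296) <= 1 and abs(len(test) - 127) <= 1
        assert len(train) + len(test) == 423

    def test_partition_is_disjoint_and_exhaustive(self, pilot_cohort):
        train, test = split_dataset(pilot_cohort, 0.7, seed=1)
        ids_train = set(train.frame.subject_id)
        ids_test = set(test.frame.subject_id)
        assert not ids_train & ids_test
        assert ids_train | ids_test == set(pilot_cohort.frame.subject_id)

    def test_stratification_keeps_originals_in_test(self, pilot_cohort):
        aug = augment_dataset(pilot_cohort, seed=0)
        _, test = split_dataset(aug, 0.7, seed=0)
        # 23 originals at a 30% test share -> about 7 land in the test side
        n_orig = (test.frame.provenance == "original").sum()
        assert 4 <= n_orig <= 10

    def test_degenerate_fraction_rejected(self, pilot_cohort):
        with pytest.raises(ValueError, match="strictly"):
            split_dataset(pilot_cohort, 1.0, seed=0)


class TestAggregate:
    def test_unanimous_positive(self):
        assert aggregate_outputs(np.ones(6)) == 1.0

    def test_alternating_outputs(self):
        assert aggregate_outputs([1, 0, 1, 0, 1, 0]) == pytest.approx(0.5)

    def test_matches_brute_force_mean(self, rng):
        vecs = rng.random((1000, 6))
        got = aggregate_outputs(vecs)
        expected = np.array([sum(v) / len(v) for v in vecs])
        assert np.allclose(got, expected, atol=1e-15)

    def test_permutation_invariant_and_bounded(self, rng):
        v = rng.random(6)
        assert aggregate_outputs(v) == pytest.approx(aggregate_outputs(v[::-1]))
        assert 0.0 <= aggregate_outputs(v) <= 1.0

    def test_missing_exercise_is_hard_error(self):
        with pytest.raises(ValueError, match="missing"):
            aggregate_outputs([0.5, np.nan, 0.5])


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 0, 1])
        rep = evaluate(y, y.astype(float))
        assert rep.sensitivity == rep.specificity == rep.accuracy == 1.0

    def test_hand_computed_confusion(self):
        # TP=7 FN=2 TN=13 FP=1
        y = np.concatenate([np.ones(9), np.zeros(14)]).astype(int)
        scores = np.concatenate([np.ones(7), np.zeros(2), np.zeros(13), np.ones(1)])
        rep = evaluate(y, scores)
        assert rep.sensitivity == pytest.approx(7 / 9)
        assert rep.specificity == pytest.approx(13 / 14)
        assert rep.accuracy == pytest.approx(20 / 23)
        assert rep.support == {"no_DN": 14, "DN": 9}

    def test_random_scores_auc_near_half(self, rng):
        n1 = n0 = 500
        y = np.repeat([0, 1], n0)
        rep = evaluate(y, rng.random(n0 + n1))
        se = np.sqrt((n0 + n1 + 1) / (12 * n0 * n1))
        assert abs(rep.auc - 0.5) < 3 * se

    def test_prevalence_weighted_accuracy_identity(self, rng):
        y = (rng.random(200) < 0.3).astype(int)
        scores = rng.random(200)
        rep = evaluate(y, scores)
        prev = y.mean()
        assert rep.accuracy == pytest.approx(
            rep.sensitivity * prev + rep.specificity * (1 - prev)
        )

    def test_single_class_truth_gives_partial_report(self):
        rep = evaluate(np.ones(5, dtype=int), np.linspace(0, 1, 5))
        assert rep.auc is None and rep.roc_fpr is None


class TestEnsemble:
    def test_aggregated_auc_not_below_best_single_exercise(self):
        """The six-model mean should discriminate at least as well as the
        best single exercise model (small slack for test-set noise)."""
        for seed in range(3):
            cohort = simulate_feature_cohort(
                CohortSimSpec(n_no_dn=60, n_dn=60, include_edx=False, seed=seed)
            )
            train, test = split_dataset(cohort, 0.7, seed=seed)
            model = ExerciseEnsembleClassifier(random_state=seed)
            model.fit(train.X, train.y)
            per_ex = model.exercise_probabilities(test.X)
            from sklearn.metrics import roc_auc_score

            single = max(roc_auc_score(test.y, per_ex[c]) for c in per_ex.columns)
            agg = roc_auc_score(test.y, model.predict_proba(test.X)[:, 1])
            assert agg >= single - 0.05

    def test_screen_reports_probability_and_call(self, pilot_cohort):
        model = ExerciseEnsembleClassifier(
            model_kind="decision_tree", p_threshold=0.9, random_state=0
        )
        model.fit(pilot_cohort.X, pilot_cohort.y)
        results = model.screen(pilot_cohort.X, pilot_cohort.frame.subject_id)
        assert len(results) == len(pilot_cohort)
        for res in results[:5]:
            assert 0.0 <= res.aggregated <= 1.0
            assert res.call in ("no_DN", "DN")
            assert res.aggregated == pytest.approx(
                np.mean(list(res.per_exercise.values()))
            )
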