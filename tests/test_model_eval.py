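"""Metric closed forms, AUROC, cross-validation and experiment designs."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import matthews_corrcoef, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from fpqsar.datasets import LABEL_ACTIVE, LABEL_INACTIVE, ActivityDataset
from fpqsar.fingerprints import FingerprintMatrix, FrequencyScoreModel
from fpqsar.model_eval import (
    ConfusionCounts,
    EvaluationReport,
    ExperimentConfig,
    LearnerSpec,
    auroc,
    confusion_counts,
    cross_validate,
    evaluate_predictions,
    experiment_matrix,
    metrics,
    train_and_test,
)
from fpqsar.synthetic import PlantedBit, SyntheticSpec, generate, make_class_structure

A, I = LABEL_ACTIVE, LABEL_INACTIVE


class TestMetrics:
    def test_perfect_classifier(self):
        rep = metrics(ConfusionCounts(tp=10, fp=0, tn=10, fn=0))
        assert (rep.sensitivity, rep.specificity, rep.accuracy) == (100.0, 100.0, 100.0)
        assert rep.mcc == pytest.approx(1.0)

    def test_inverted_predictions_give_mcc_minus_one(self):
        rep = metrics(ConfusionCounts(tp=0, fp=10, tn=0, fn=10))
        assert rep.mcc == pytest.approx(-1.0)

    def test_closed_form_example(self):
        rep = metrics(ConfusionCounts(tp=3, fp=1, tn=2, fn=2))
        assert rep.accuracy == pytest.approx(62.5)
        assert rep.mcc == pytest.approx(4 / math.sqrt(240))

    def test_zero_denominator_mcc_defined_as_zero(self):
        rep = metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=5))
        assert rep.mcc == 0.0

    def test_scale_invariance(self):
        base = metrics(ConfusionCounts(tp=3, fp=1, tn=2, fn=2))
        scaled = metrics(ConfusionCounts(tp=30, fp=10, tn=20, fn=20))
        for attr in ("sensitivity", "specificity", "accuracy", "mcc"):
            assert getattr(scaled, attr) == pytest.approx(getattr(base, attr))

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.tuples(*[st.integers(0, 40)] * 4))
    def test_mcc_matches_sklearn(self, counts):
        tp, fp, tn, fn = counts
        if tp + fp + tn + fn == 0:
            return
        y_true = [1] * tp + [0] * fp + [0] * tn + [1] * fn
        y_pred = [1] * tp + [1] * fp + [0] * tn + [0] * fn
        rep = metrics(ConfusionCounts(tp, fp, tn, fn))
        assert rep.mcc == pytest.approx(matthews_corrcoef(y_true, y_pred), abs=1e-12)
        assert -1 <= rep.mcc <= 1

    def test_confusion_counts_from_labels(self):
        counts = confusion_counts([A, A, I, I, A], [A, I, I, A, A])
        assert (counts.tp, counts.fn, counts.tn, counts.fp) == (2, 1, 1, 1)

    def test_report_round_trip(self):
        rep = metrics(ConfusionCounts(3, 1, 2, 2), auroc_value=0.75, experiment_tag="x")
        assert EvaluationReport.from_dict(rep.to_dict()) == rep


def brute_force_auroc(scores, labels):
    """Oracle: enumerate all (inhibitor, non-inhibitor) pairs, ties count 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == A]
    neg = [s for s, l in zip(scores, labels) if l == I]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0.9, 0.8, 0.2, 0.1], [A, A, I, I]) == 1.0

    def test_all_scores_identical(self):
        assert auroc([0.5] * 6, [A, A, A, I, I, I]) == 0.5

    def test_enumerated_example(self):
        # actives {0.9, 0.4}, inactives {0.8, 0.1}: 3 wins of 4 pairs
        assert auroc([0.9, 0.4, 0.8, 0.1], [A, A, I, I]) == pytest.approx(0.75)

    def test_single_class_is_error(self):
        with pytest.raises(ValueError, match="one class"):
            auroc([0.5, 0.6], [A, A])

    def test_matches_pair_enumeration_and_sklearn(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            n = int(rng.integers(4, 100))
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)  # force ties
            labels = [A, I] + [A if rng.uniform() < 0.5 else I for _ in range(n - 2)]
            got = auroc(scores, labels)
            assert got == pytest.approx(brute_force_auroc(scores, labels))
            y = [1 if l == A else 0 for l in labels]
            assert got == pytest.approx(roc_auc_score(y, scores))

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(14)
        scores = rng.uniform(size=30)
        labels = [A if rng.uniform() < 0.5 else I for _ in range(28)] + [A, I]
        swapped = [I if l == A else A for l in labels]
        assert auroc(scores, swapped) == pytest.approx(1 - auroc(scores, labels))

    def test_prediction_label_swap_keeps_accuracy_swaps_sens_spec(self):
        rng = np.random.default_rng(15)
        y_true = [A if rng.uniform() < 0.4 else I for _ in range(50)]
        y_pred = [A if rng.uniform() < 0.5 else I for _ in range(50)]
        swap = {A: I, I: A}
        fwd = metrics(confusion_counts(y_true, y_pred))
        rev = metrics(confusion_counts([swap[l] for l in y_true],
                                       [swap[l] for l in y_pred]))
        assert rev.accuracy == pytest.approx(fwd.accuracy)
        assert rev.sensitivity == pytest.approx(fwd.specificity)
        assert rev.specificity == pytest.approx(fwd.sensitivity)


def small_separable(seed=0, n=60):
    """Tiny nearly-separable benchmark for fast harness checks."""
    spec = SyntheticSpec(
        n_active=n, n_inactive=n, n_descriptors=30,
        planted_positive=[PlantedBit(i, 0.95, 0.05) for i in range(3)],
        planted_negative=[PlantedBit(i, 0.05, 0.95) for i in range(3, 6)],
        background_p=0.3, seed=seed,
    )
    return generate(spec)


class TestCrossValidate:
    def test_deterministic_given_seed(self):
        ds, fm, _ = small_separable()
        spec = LearnerSpec("random_forest", {"n_trees": 20})
        a, _ = cross_validate(ds, fm, spec, k=3, repeats=2, seed=5)
        b, _ = cross_validate(ds, fm, spec, k=3, repeats=2, seed=5)
        assert a == b

    def test_every_compound_tested_once_per_repeat(self):
        ds, fm, _ = small_separable()
        _, folds = cross_validate(
            ds, fm, LearnerSpec("naive_bayes"), k=4, repeats=2, seed=1
        )
        per_repeat = len(ds)
        totals = [r.counts.total for r in folds]
        assert sum(totals[:4]) == per_repeat and sum(totals[4:]) == per_repeat

    def test_separable_data_classified_accurately(self):
        ds, fm, _ = small_separable()
        mean, _ = cross_validate(
            ds, fm, LearnerSpec("random_forest"), k=5, repeats=1, seed=0
        )
        assert mean.accuracy > 95.0

    def test_repeats_one_equals_mean_of_manual_folds(self):
        # with a deterministic learner, one repeat of k-fold CV is the mean of
        # k independent train/test evaluations on the same folds
        ds, fm, _ = small_separable(seed=3)
        seed = 7
        mean, folds = cross_validate(
            ds, fm, LearnerSpec("sum_score", {"k_pos": 3, "k_neg": 3}),
            k=3, repeats=1, seed=seed,
        )
        frame = fm.align_to(ds).values
        y = ds.labels.to_numpy()
        splitter = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
        manual = []
        for tr, te in splitter.split(frame, y):
            res = FrequencyScoreModel(
                FingerprintMatrix(frame.iloc[tr]), y[tr], k_pos=3, k_neg=3
            ).fit()
            clf = res.as_classifier()
            pred = clf.predict_labels(frame.iloc[te]).to_numpy()
            manual.append(evaluate_predictions(y[te], pred,
                                               clf.scores(frame.iloc[te])))
        assert mean.mcc == pytest.approx(np.mean([m.mcc for m in manual]))
        assert mean.accuracy == pytest.approx(np.mean([m.accuracy for m in manual]))

    def test_class_smaller_than_k_is_error(self):
        ds, fm, _ = small_separable(n=60)
        tiny = ActivityDataset(
            cutoff_nm=ds.cutoff_nm,
            compounds=pd.concat(
                [ds.compounds[ds.compounds.label == A].head(3),
                 ds.compounds[ds.compounds.label == I].head(30)]
            ).reset_index(drop=True),
        )
        with pytest.raises(ValueError, match="cannot make 5 folds"):
            cross_validate(tiny, fm, LearnerSpec("naive_bayes"), k=5, repeats=1, seed=0)


class TestTrainAndTest:
    def test_overlapping_sets_rejected(self):
        ds, fm, _ = small_separable()
        with pytest.raises(ValueError, match="overlap"):
            train_and_test(ds, ds, fm, fm, LearnerSpec("naive_bayes"))

    def test_descriptor_mismatch_rejected(self):
        ds, fm, _ = small_separable()
        half_a = ActivityDataset(cutoff_nm=10,
                                 compounds=ds.compounds.iloc[:60].reset_index(drop=True))
        half_b = ActivityDataset(cutoff_nm=10,
                                 compounds=ds.compounds.iloc[60:].reset_index(drop=True))
        shuffled = FingerprintMatrix(fm.values[list(fm.values.columns[::-1])])
        with pytest.raises(ValueError, match="descriptor columns"):
            train_and_test(half_a, half_b, fm, shuffled, LearnerSpec("naive_bayes"))

    def test_sum_score_learner_matches_manual_pipeline(self):
        ds, fm, _ = small_separable(seed=4)
        half_a = ActivityDataset(cutoff_nm=10,
                                 compounds=ds.compounds.iloc[::2].reset_index(drop=True))
        half_b = ActivityDataset(cutoff_nm=10,
                                 compounds=ds.compounds.iloc[1::2].reset_index(drop=True))
        report = train_and_test(
            half_a, half_b, fm, fm, LearnerSpec("sum_score", {"k_pos": 3, "k_neg": 3})
        )
        res = FrequencyScoreModel.from_dataset(half_a, fm, k_pos=3, k_neg=3).fit()
        clf = res.as_classifier()
        test_frame = fm.align_to(half_b).values
        manual = evaluate_predictions(
            half_b.labels.to_numpy(),
            clf.predict_labels(test_frame).to_numpy(),
            clf.scores(test_frame),
        )
        assert report.counts == manual.counts
        assert report.mcc == pytest.approx(manual.mcc)


def class_structured(seed=0):
    spec = SyntheticSpec(
        n_active=40, n_inactive=40, n_descriptors=25,
        planted_positive=[PlantedBit(i, 0.9, 0.1) for i in range(3)],
        planted_negative=[PlantedBit(i, 0.1, 0.9) for i in range(3, 6)],
        background_p=0.3, seed=seed,
    )
    return make_class_structure(spec, class_fraction=0.3, class_marker_index=20)


class TestExperimentMatrix:
    def test_no_classes_gives_base_reports_only(self):
        ds, fm, _ = small_separable()
        config = ExperimentConfig(
            ds=ds, fm=fm, learner=LearnerSpec("naive_bayes"),
            class_names=[], k=3, repeats=1, seed=0,
        )
        reports = experiment_matrix(config)
        assert [r.experiment_tag for r in reports] == ["train CV", "train vs validation"]

    def test_one_class_grid_shape(self):
        ds, fm, _ = class_structured()
        config = ExperimentConfig(
            ds=ds, fm=fm, learner=LearnerSpec("naive_bayes"),
            class_names=["pyrimidine"], k=3, repeats=1, seed=0,
        )
        reports = experiment_matrix(config)
        tags = [r.experiment_tag for r in reports]
        assert tags == [
            "train CV",
            "train vs validation",
            "pyrimidine CV",
            "pyrimidine vs rest",
            "without-pyrimidine CV",
            "without-pyrimidine vs pyrimidine",
        ]

    def test_leave_class_out_generalises_to_held_out_class(self):
        # the held-out class shares the planted signal, so the complement
        # model must beat chance on it
        ds, fm, _ = class_structured(seed=2)
        config = ExperimentConfig(
            ds=ds, fm=fm, learner=LearnerSpec("random_forest", {"n_trees": 50}),
            class_names=["pyrimidine"], k=3, repeats=1, seed=2,
        )
        reports = {r.experiment_tag: r for r in experiment_matrix(config)}
        assert reports["without-pyrimidine vs pyrimidine"].mcc > 0

    def test_reports_serialise_losslessly(self):
        ds, fm, _ = small_separable()
        config = ExperimentConfig(ds=ds, fm=fm, learner=LearnerSpec("naive_bayes"),
                                  k=3, repeats=1)
        reports = experiment_matrix(config)
        for rep in reports:
            assert EvaluationReport.from_dict(rep.to_dict()) == rep
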