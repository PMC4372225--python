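"""Classifier training and evaluation harness.

Metric closed forms (sensitivity, specificity, accuracy, MCC, Mann-Whitney
AUROC), repeated stratified k-fold cross-validation, train-on-A/test-on-B
evaluation, and the scaffold-class experiment grid (class-specific models,
leave-class-out generalisation).  Learners are interchangeable behind
:class:`LearnerSpec`; the default is a 100-tree random forest, with the
frequency-selected sum-score rule available as a learner so that its
fingerprint selection is honestly re-run inside every training fold.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import BernoulliNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .datasets import (
    LABEL_ACTIVE,
    LABEL_INACTIVE,
    ActivityDataset,
    ClassDefinition,
    DEFAULT_CLASS_REGISTRY,
    class_subset,
    leave_class_out,
    train_validation_split,
)
from .fingerprints import (
    FingerprintMatrix,
    FrequencyScoreModel,
)

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts with the inhibitor class as positive."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class EvaluationReport:
    """Metrics for one experiment (one row of a performance table).

    Percent sensitivity/specificity/accuracy, MCC in [-1, 1] and AUROC in
    [0, 1] (None when the learner exposes no usable score or a class is
    absent).
    """

    counts: ConfusionCounts
    sensitivity: float
    specificity: float
    accuracy: float
    mcc: float
    auroc: float | None = None
    experiment_tag: str = ""

    def to_dict(self) -> dict:
        return {
            "experiment": self.experiment_tag,
            "tp": self.counts.tp,
            "fp": self.counts.fp,
            "tn": self.counts.tn,
            "fn": self.counts.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "mcc": self.mcc,
            "roc": self.auroc,
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "EvaluationReport":
        return cls(
            counts=ConfusionCounts(obj["tp"], obj["fp"], obj["tn"], obj["fn"]),
            sensitivity=obj["sensitivity"],
            specificity=obj["specificity"],
            accuracy=obj["accuracy"],
            mcc=obj["mcc"],
            auroc=obj.get("roc"),
            experiment_tag=obj.get("experiment", ""),
        )

    def summary(self) -> str:
        roc = "NA" if self.auroc is None else f"{self.auroc:.2f}"
        return (
            f"{self.experiment_tag or 'experiment'}: "
            f"sensitivity {self.sensitivity:.2f}  specificity {self.specificity:.2f}  "
            f"accuracy {self.accuracy:.2f}  MCC {self.mcc:.2f}  ROC {roc}"
        )


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    t = np.asarray(y_true) == LABEL_ACTIVE
    p = np.asarray(y_pred) == LABEL_ACTIVE
    return ConfusionCounts(
        tp=int((t & p).sum()),
        fp=int((~t & p).sum()),
        tn=int((~t & ~p).sum()),
        fn=int((t & ~p).sum()),
    )


def metrics(counts: ConfusionCounts, auroc_value: float | None = None,
            experiment_tag: str = "") -> EvaluationReport:
    """Closed-form metrics from confusion counts.

    MCC = (tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn)), defined as 0
    when any factor under the square root is zero.  Sensitivity/specificity
    are defined as 0 when their denominator is zero (single-class input).
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    if counts.total == 0:
        raise ValueError("cannot compute metrics on zero evaluated compounds")
    sens = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    spec = 100.0 * tn / (tn + fp) if tn + fp else 0.0
    acc = 100.0 * (tp + tn) / counts.total
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return EvaluationReport(
        counts=counts,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        mcc=mcc,
        auroc=auroc_value,
        experiment_tag=experiment_tag,
    )


def auroc(scores, labels) -> float:
    """Mann-Whitney AUROC: probability that a random inhibitor outscores a
    random non-inhibitor, counting ties as 1/2 (midrank formulation)."""
    scores = np.asarray(scores, dtype=float)
    active = np.asarray(labels) == LABEL_ACTIVE
    n_pos, n_neg = int(active.sum()), int((~active).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined: one class is absent")
    ranks = rankdata(scores)  # midranks handle ties
    u = ranks[active].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


# --------------------------------------------------------------------------
# learners
# --------------------------------------------------------------------------


@dataclass
class LearnerSpec:
    """A named learner plus hyperparameters and a seed.

    Built-in names: ``random_forest`` (default, 100 trees), ``naive_bayes``
    (Bernoulli), ``knn``, ``svm`` (RBF SVC), ``sum_score`` (the frequency
    selection + signed-sum rule, refit per training set).
    """

    name: str = "random_forest"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def build(self) -> "_Learner":
        hp = dict(self.hyperparameters)
        if self.name == "random_forest":
            return _SklearnLearner(
                RandomForestClassifier(
                    n_estimators=hp.pop("n_trees", 100),
                    random_state=self.seed,
                    n_jobs=1,
                    **hp,
                )
            )
        if self.name == "naive_bayes":
            return _SklearnLearner(BernoulliNB(**hp))
        if self.name == "knn":
            return _SklearnLearner(KNeighborsClassifier(**hp))
        if self.name == "svm":
            hp.setdefault("probability", False)
            return _SklearnLearner(SVC(random_state=self.seed, **hp))
        if self.name == "sum_score":
            return _SumScoreLearner(
                correlation_threshold=hp.pop("correlation_threshold", 0.6),
                k_pos=hp.pop("k_pos", 10),
                k_neg=hp.pop("k_neg", 10),
                decision_threshold=hp.pop("decision_threshold", 1),
            )
        raise ValueError(f"unknown learner {self.name!r}")

    def reseeded(self, seed: int) -> "LearnerSpec":
        return replace(self, seed=seed)


class _Learner:
    """fit / predict_labels / decision_scores contract used by the harness."""

    def fit(self, frame: pd.DataFrame, labels: np.ndarray) -> "_Learner":
        raise NotImplementedError

    def predict_labels(self, frame: pd.DataFrame) -> np.ndarray:
        raise NotImplementedError

    def decision_scores(self, frame: pd.DataFrame) -> np.ndarray | None:
        """Real-valued score, larger = more inhibitor-like; None if unavailable."""
        raise NotImplementedError


class _SklearnLearner(_Learner):
    def __init__(self, estimator) -> None:
        self.estimator = estimator

    def fit(self, frame, labels):
        y = (np.asarray(labels) == LABEL_ACTIVE).astype(int)
        self.estimator.fit(frame.to_numpy(), y)
        return self

    def predict_labels(self, frame):
        y = self.estimator.predict(frame.to_numpy())
        return np.where(y == 1, LABEL_ACTIVE, LABEL_INACTIVE)

    def decision_scores(self, frame):
        X = frame.to_numpy()
        if hasattr(self.estimator, "predict_proba"):
            proba = self.estimator.predict_proba(X)
            idx = list(self.estimator.classes_).index(1)
            return proba[:, idx]
        if hasattr(self.estimator, "decision_function"):
            return np.asarray(self.estimator.decision_function(X), dtype=float)
        return None


class _SumScoreLearner(_Learner):
    """The published pipeline as a learner: phi redundancy filter and best-k
    frequency selection on the *training* data only, then the signed sum."""

    def __init__(self, correlation_threshold=0.6, k_pos=10, k_neg=10,
                 decision_threshold=1) -> None:
        self.correlation_threshold = correlation_threshold
        self.k_pos = k_pos
        self.k_neg = k_neg
        self.decision_threshold = decision_threshold
        self.model_ = None

    def fit(self, frame, labels):
        res = FrequencyScoreModel(
            FingerprintMatrix(frame),
            labels,
            correlation_threshold=self.correlation_threshold,
            k_pos=self.k_pos,
            k_neg=self.k_neg,
        ).fit()
        self.model_ = res.as_classifier(self.decision_threshold)
        return self

    def predict_labels(self, frame):
        return self.model_.predict_labels(frame).to_numpy()

    def decision_scores(self, frame):
        return self.model_.scores(frame).to_numpy(dtype=float)


def evaluate_predictions(y_true, y_pred, scores=None, tag="") -> EvaluationReport:
    """Confusion counts + metrics (+ AUROC when scores are available and both
    classes are present)."""
    roc = None
    if scores is not None and len(set(np.asarray(y_true))) == 2:
        roc = auroc(scores, y_true)
    return metrics(confusion_counts(y_true, y_pred), auroc_value=roc, experiment_tag=tag)


# --------------------------------------------------------------------------
# experiment designs
# --------------------------------------------------------------------------


def _aligned(ds: ActivityDataset, fm: FingerprintMatrix) -> pd.DataFrame:
    return fm.align_to(ds).values


def cross_validate(
    ds: ActivityDataset,
    fm: FingerprintMatrix,
    learner: LearnerSpec,
    k: int = 5,
    repeats: int = 5,
    seed: int = 0,
    tag: str | None = None,
) -> tuple[EvaluationReport, list[EvaluationReport]]:
    """Stratified k-fold cross-validation repeated ``repeats`` times.

    Every fit — including the sum-score learner's fingerprint selection —
    sees only the training folds.  Fold metrics are macro-averaged over the
    k × repeats test folds; the pooled confusion counts are reported
    alongside.  Deterministic given ``seed``.
    """
    frame = _aligned(ds, fm)
    y = ds.labels.to_numpy()
    n_min = min(ds.n_active, ds.n_inactive)
    if n_min < k:
        raise ValueError(f"smallest class has {n_min} compounds; cannot make {k} folds")

    fold_reports: list[EvaluationReport] = []
    for rep in range(repeats):
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + rep)
        for fold, (tr, te) in enumerate(splitter.split(frame, y)):
            fitted = learner.reseeded(seed + rep).build().fit(frame.iloc[tr], y[tr])
            pred = fitted.predict_labels(frame.iloc[te])
            scores = fitted.decision_scores(frame.iloc[te])
            fold_reports.append(
                evaluate_predictions(
                    y[te], pred, scores, tag=f"repeat{rep}_fold{fold}"
                )
            )

    mean = _macro_average(fold_reports, tag or f"{learner.name} {k}-fold CV x{repeats}")
    return mean, fold_reports


def _macro_average(reports: list[EvaluationReport], tag: str) -> EvaluationReport:
    pooled = ConfusionCounts(
        tp=sum(r.counts.tp for r in reports),
        fp=sum(r.counts.fp for r in reports),
        tn=sum(r.counts.tn for r in reports),
        fn=sum(r.counts.fn for r in reports),
    )
    rocs = [r.auroc for r in reports if r.auroc is not None]
    return EvaluationReport(
        counts=pooled,
        sensitivity=float(np.mean([r.sensitivity for r in reports])),
        specificity=float(np.mean([r.specificity for r in reports])),
        accuracy=float(np.mean([r.accuracy for r in reports])),
        mcc=float(np.mean([r.mcc for r in reports])),
        auroc=float(np.mean(rocs)) if rocs else None,
        experiment_tag=tag,
    )


def train_and_test(
    train_ds: ActivityDataset,
    test_ds: ActivityDataset,
    fm_train: FingerprintMatrix,
    fm_test: FingerprintMatrix,
    learner: LearnerSpec,
    tag: str | None = None,
) -> EvaluationReport:
    """Fit on one dataset, report on a disjoint one (transfer evaluation)."""
    overlap = set(train_ds.compound_ids) & set(test_ds.compound_ids)
    if overlap:
        raise ValueError(f"train and test compound sets overlap: {sorted(overlap)[:5]}")
    if list(fm_train.descriptor_names) != list(fm_test.descriptor_names):
        raise ValueError("train and test descriptor columns differ (names or order)")
    X_train = _aligned(train_ds, fm_train)
    X_test = _aligned(test_ds, fm_test)
    fitted = learner.build().fit(X_train, train_ds.labels.to_numpy())
    pred = fitted.predict_labels(X_test)
    scores = fitted.decision_scores(X_test)
    tag = tag or f"trained-on-{train_ds.split_tag} tested-on-{test_ds.split_tag}"
    return evaluate_predictions(test_ds.labels.to_numpy(), pred, scores, tag=tag)


@dataclass
class ExperimentConfig:
    """One run of the scaffold-class experiment grid."""

    ds: ActivityDataset
    fm: FingerprintMatrix
    learner: LearnerSpec = field(default_factory=LearnerSpec)
    class_names: list[str] = field(default_factory=list)
    registry: list[ClassDefinition] = field(default_factory=lambda: list(DEFAULT_CLASS_REGISTRY))
    validation_fraction: float = 0.1
    k: int = 5
    repeats: int = 5
    seed: int = 0


def experiment_matrix(config: ExperimentConfig) -> list[EvaluationReport]:
    """Run the full experiment grid and return one report per row.

    Rows: (1) CV on the train split, (2) train-split model on the validation
    split; then per class c: CV on the class subset, class model tested on
    the other classes' pool, CV on the leave-class-out complement, and the
    leave-class-out model tested on the held-out class.
    """
    ds, fm = config.ds, config.fm
    train, validation = train_validation_split(
        ds, config.validation_fraction, seed=config.seed
    )
    reports: list[EvaluationReport] = []
    cv_mean, _ = cross_validate(
        train, fm, config.learner, k=config.k, repeats=config.repeats,
        seed=config.seed, tag="train CV",
    )
    reports.append(cv_mean)
    reports.append(
        train_and_test(train, validation, fm, fm, config.learner,
                       tag="train vs validation")
    )

    for class_name in config.class_names:
        inside = class_subset(ds, class_name, config.registry)
        outside = leave_class_out(ds, class_name, config.registry)

        # cross-class target: the other named classes where given, else the
        # whole complement
        others = [c for c in config.class_names if c != class_name]
        if others:
            cross_frames = [
                class_subset(ds, other, config.registry).compounds for other in others
            ]
            cross_ds = ActivityDataset(
                cutoff_nm=ds.cutoff_nm,
                compounds=pd.concat(cross_frames, ignore_index=True),
                split_tag="cross_class",
            )
            cross_tag = f"{class_name} vs {'+'.join(others)}"
        else:
            cross_ds, cross_tag = outside, f"{class_name} vs rest"

        cv_in, _ = cross_validate(
            inside, fm, config.learner, k=config.k, repeats=config.repeats,
            seed=config.seed, tag=f"{class_name} CV",
        )
        reports.append(cv_in)
        reports.append(
            train_and_test(inside, cross_ds, fm, fm, config.learner, tag=cross_tag)
        )
        cv_out, _ = cross_validate(
            outside, fm, config.learner, k=config.k, repeats=config.repeats,
            seed=config.seed, tag=f"without-{class_name} CV",
        )
        reports.append(cv_out)
        reports.append(
            train_and_test(outside, inside, fm, fm, config.learner,
                           tag=f"without-{class_name} vs {class_name}")
        )
    return reports


def reports_to_frame(reports: list[EvaluationReport]) -> pd.DataFrame:
    """Tabulate reports with the canonical column layout."""
    frame = pd.DataFrame([r.to_dict() for r in reports])
    return frame[["experiment", "sensitivity", "specificity", "accuracy", "mcc", "roc"]]


def write_reports(reports: list[EvaluationReport], json_path=None, tsv_path=None) -> None:
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump([r.to_dict() for r in reports], fh, indent=2)
            fh.write("\n")
    if tsv_path is not None:
        reports_to_frame(reports).to_csv(tsv_path, sep="\t", index=False)
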