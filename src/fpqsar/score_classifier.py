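"""The interpretable sum-score classifier.

Given the selected best fingerprints, each compound's score is the number of
its set *positive* bits (enriched in inhibitors) minus the number of its set
*negative* bits (enriched in non-inhibitors).  A compound is predicted an
inhibitor when the score reaches the decision threshold; the published rule
uses t = 1, so a balanced compound (score 0) is a non-inhibitor.

The threshold sweep tabulates sensitivity / specificity / accuracy / MCC at
every integer threshold over the observed score range, which is how the
balance point t = 1 was chosen in the first place.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import LABEL_ACTIVE, LABEL_INACTIVE
from .fingerprints import FingerprintMatrix


@dataclass
class SumScoreModel:
    """Signed unit-weight sum over a selected fingerprint panel.

    score(x) = #{positive bits set} - #{negative bits set};
    predict inhibitor iff score >= decision_threshold (default 1).
    """

    positive_names: list[str]
    negative_names: list[str]
    decision_threshold: int = 1

    def __post_init__(self) -> None:
        overlap = set(self.positive_names) & set(self.negative_names)
        if overlap:
            raise ValueError(f"descriptors on both sides of the model: {sorted(overlap)}")

    @property
    def score_range(self) -> tuple[int, int]:
        return (-len(self.negative_names), len(self.positive_names))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "positive": self.positive_names,
                    "negative": self.negative_names,
                    "threshold": self.decision_threshold,
                },
                indent=2,
            )
            + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SumScoreModel":
        obj = json.loads(Path(path).read_text())
        return cls(
            positive_names=list(obj["positive"]),
            negative_names=list(obj["negative"]),
            decision_threshold=int(obj.get("threshold", 1)),
        )

    # vectorised scoring -------------------------------------------------

    def scores(self, fm: FingerprintMatrix | pd.DataFrame) -> pd.Series:
        """Integer sum score for every compound (row) of a matrix."""
        frame = fm.values if isinstance(fm, FingerprintMatrix) else fm
        missing = (set(self.positive_names) | set(self.negative_names)) - set(frame.columns)
        if missing:
            raise KeyError(f"matrix lacks model descriptors: {sorted(missing)}")
        pos = frame[self.positive_names].to_numpy().sum(axis=1) if self.positive_names else 0
        neg = frame[self.negative_names].to_numpy().sum(axis=1) if self.negative_names else 0
        return pd.Series(pos - neg, index=frame.index, name="sum_score", dtype=int)

    def predict_labels(self, fm: FingerprintMatrix | pd.DataFrame) -> pd.Series:
        s = self.scores(fm)
        return pd.Series(
            np.where(s >= self.decision_threshold, LABEL_ACTIVE, LABEL_INACTIVE),
            index=s.index,
            name="label",
        )


def sum_score(model: SumScoreModel, fingerprint_row) -> int:
    """Score a single compound from its named bits (mapping or Series)."""
    for name in (*model.positive_names, *model.negative_names):
        if name not in fingerprint_row:
            raise KeyError(f"fingerprint row is missing descriptor {name!r}")
    pos = sum(int(fingerprint_row[n]) for n in model.positive_names)
    neg = sum(int(fingerprint_row[n]) for n in model.negative_names)
    return pos - neg


def predict(model: SumScoreModel, fingerprint_row) -> str:
    """Label a single compound: inhibitor iff score >= decision threshold."""
    return (
        LABEL_ACTIVE
        if sum_score(model, fingerprint_row) >= model.decision_threshold
        else LABEL_INACTIVE
    )


def threshold_sweep(
    model: SumScoreModel, fm: FingerprintMatrix | pd.DataFrame, labels
) -> pd.DataFrame:
    """Performance at every integer decision threshold over the score range.

    Returns one row per threshold t from (min observed score) to
    (max observed score + 1) with sensitivity, specificity, accuracy
    (percent) and MCC, so both degenerate endpoints (everything predicted
    inhibitor / nothing predicted inhibitor) appear.
    """
    from .model_eval import confusion_counts, metrics

    frame = fm.values if isinstance(fm, FingerprintMatrix) else fm
    labels = np.asarray(
        labels.reindex(frame.index) if isinstance(labels, pd.Series) else labels
    )
    if len(set(labels)) < 2:
        raise ValueError("threshold sweep needs both label classes present")
    s = model.scores(frame).to_numpy()

    rows = []
    for t in range(int(s.min()), int(s.max()) + 2):
        pred = np.where(s >= t, LABEL_ACTIVE, LABEL_INACTIVE)
        rep = metrics(confusion_counts(labels, pred))
        rows.append(
            {
                "threshold": t,
                "sensitivity": rep.sensitivity,
                "specificity": rep.specificity,
                "accuracy": rep.accuracy,
                "mcc": rep.mcc,
            }
        )
    return pd.DataFrame(rows)
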